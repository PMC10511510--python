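"""Patch-wise and downsampled single-shot 3D inference over pluggable predictors.

Tumor models run iteratively over fixed-size patches (default 160^3 voxels)
tiled across the volume, with overlapping predictions fused into one
probability map. Brain extraction instead runs one single-shot prediction on
a downsampled copy of the whole scan and upsamples the probability map back
to the native grid. Both paths are agnostic to the predictor: anything that
maps a scalar patch to a same-shape probability map in [0, 1] plugs in
(e.g. an ONNX-runtime wrapper around trained weights, or the synthetic
threshold predictor used in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, PredictorContractError
from .image_core import LabelMask, VolumetricImage

__all__ = [
    "Predictor",
    "FunctionPredictor",
    "PatchGrid",
    "plan_patch_grid",
    "predict_patchwise",
    "predict_downsampled",
    "binarize_probability",
]

DEFAULT_PATCH_SHAPE = (160, 160, 160)


@runtime_checkable
class Predictor(Protocol):
    """Voxel classifier contract: patch in -> same-shape probabilities in [0,1]."""

    input_patch_shape: tuple[int, int, int]

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


@dataclass
class FunctionPredictor:
    """Wrap a plain array function as a :class:`Predictor`."""

    fn: Callable[[np.ndarray], np.ndarray]
    input_patch_shape: tuple[int, int, int] = DEFAULT_PATCH_SHAPE

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.fn(patch)


@dataclass(frozen=True)
class PatchGrid:
    """Tiling plan: patch shape, corner indices, and symmetric padding."""

    patch_shape: tuple[int, int, int]
    starts: tuple[tuple[int, int, int], ...]
    padding: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    volume_shape: tuple[int, int, int]

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(s + lo + hi for s, (lo, hi) in zip(self.volume_shape, self.padding))

    def __len__(self) -> int:
        return len(self.starts)


def _axis_starts(length: int, patch: int, min_overlap_fraction: float) -> list[int]:
    if length <= patch:
        return [0]
    # smallest count n achieving full coverage with per-pair overlap >= the
    # requested fraction; starts spread evenly, first at 0, last flush with
    # the far edge
    step_max = patch * (1.0 - min_overlap_fraction)
    n = int(np.ceil((length - patch) / step_max)) + 1
    starts = np.round(np.linspace(0, length - patch, n)).astype(int)
    return sorted(set(int(s) for s in starts))


def plan_patch_grid(
    volume_shape: Sequence[int],
    patch_shape: Sequence[int] = DEFAULT_PATCH_SHAPE,
    min_overlap_fraction: float = 0.0,
) -> PatchGrid:
    """Plan a deterministic patch tiling that covers every voxel.

    A volume smaller than the patch along an axis is symmetrically padded to
    the patch size (constant 0 background, consistent with [0,1]-normalized
    inputs) and covered by a single patch on that axis.
    """
    vshape = tuple(int(s) for s in volume_shape)
    pshape = tuple(int(s) for s in patch_shape)
    if len(vshape) != 3 or len(pshape) != 3:
        raise InvalidParameterError("volume_shape and patch_shape must be 3D")
    if any(p <= 0 for p in pshape) or any(v <= 0 for v in vshape):
        raise InvalidParameterError("shapes must be positive")
    if not (0 <= min_overlap_fraction < 1):
        raise InvalidParameterError("min_overlap_fraction must be in [0, 1)")
    padding = []
    for v, p in zip(vshape, pshape):
        deficit = max(0, p - v)
        padding.append((deficit // 2, deficit - deficit // 2))
    padded = tuple(v + lo + hi for v, (lo, hi) in zip(vshape, padding))
    per_axis = [_axis_starts(L, p, min_overlap_fraction) for L, p in zip(padded, pshape)]
    starts = tuple(
        (i, j, k) for i in per_axis[0] for j in per_axis[1] for k in per_axis[2]
    )
    return PatchGrid(pshape, starts, tuple(padding), vshape)


def _run_predictor(predictor: Predictor, patch: np.ndarray) -> np.ndarray:
    out = np.asarray(predictor(patch), dtype=float)
    if out.shape != patch.shape:
        raise PredictorContractError(
            f"predictor returned shape {out.shape} for patch shape {patch.shape}"
        )
    if out.size and (out.min() < -1e-9 or out.max() > 1 + 1e-9):
        raise PredictorContractError("predictor probabilities must lie in [0, 1]")
    return np.clip(out, 0.0, 1.0)


def predict_patchwise(
    image: VolumetricImage,
    predictor: Predictor,
    grid: PatchGrid | None = None,
    fusion: Literal["mean", "max"] = "mean",
) -> VolumetricImage:
    """Iterate the predictor over the patch grid and fuse into one map."""
    if fusion not in ("mean", "max"):
        raise InvalidParameterError(f"unknown fusion {fusion!r}")
    if grid is None:
        grid = plan_patch_grid(image.shape, getattr(predictor, "input_patch_shape", DEFAULT_PATCH_SHAPE))
    pshape = getattr(predictor, "input_patch_shape", None)
    if pshape is not None and tuple(pshape) != tuple(grid.patch_shape):
        raise PredictorContractError(
            f"predictor patch shape {tuple(pshape)} != grid patch shape {grid.patch_shape}"
        )
    padded = np.pad(np.asarray(image.voxels, dtype=float), grid.padding, constant_values=0.0)
    if fusion == "mean":
        acc = np.zeros_like(padded)
        count = np.zeros(padded.shape, dtype=np.int32)
    else:
        acc = np.full_like(padded, -np.inf)
        count = np.zeros(padded.shape, dtype=np.int32)
    p0, p1, p2 = grid.patch_shape
    for (i, j, k) in grid.starts:
        sl = (slice(i, i + p0), slice(j, j + p1), slice(k, k + p2))
        pred = _run_predictor(predictor, padded[sl])
        if fusion == "mean":
            acc[sl] += pred
        else:
            acc[sl] = np.maximum(acc[sl], pred)
        count[sl] += 1
    if count.min() < 1:
        raise PredictorContractError("patch grid does not cover every voxel")
    prob = acc / count if fusion == "mean" else acc
    crop = tuple(
        slice(lo, lo + s) for (lo, _), s in zip(grid.padding, grid.volume_shape)
    )
    return image.with_voxels(np.clip(prob[crop], 0.0, 1.0))


def predict_downsampled(
    image: VolumetricImage,
    predictor: Predictor,
    working_shape: Sequence[int],
    threshold: float = 0.5,
    kind: str = "brain",
) -> LabelMask:
    """Single-shot inference on a downsampled copy, upsampled back and binarized."""
    wshape = tuple(int(s) for s in working_shape)
    if any(s <= 0 for s in wshape):
        raise InvalidParameterError("working_shape must be positive")
    vox = np.asarray(image.voxels, dtype=float)
    if wshape == image.shape:
        small = vox
    else:
        small = ndimage.zoom(
            vox, np.array(wshape) / np.array(image.shape),
            order=1, mode="nearest", grid_mode=True, prefilter=False,
        )
    pshape = getattr(predictor, "input_patch_shape", None)
    if pshape is not None and tuple(pshape) != wshape:
        raise PredictorContractError(
            f"predictor patch shape {tuple(pshape)} != working shape {wshape}"
        )
    prob = _run_predictor(predictor, small)
    if wshape != image.shape:
        prob = ndimage.zoom(
            prob, np.array(image.shape) / np.array(wshape),
            order=1, mode="nearest", grid_mode=True, prefilter=False,
        )
        prob = np.clip(prob, 0.0, 1.0)
    return binarize_probability(image.with_voxels(prob), threshold, kind=kind)


def binarize_probability(
    prob: VolumetricImage, threshold: float = 0.5, kind: str = "tumor"
) -> LabelMask:
    """Threshold a probability map into a binary mask (label 1 where p >= t)."""
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError("threshold must lie in [0, 1]")
    v = np.asarray(prob.voxels, dtype=float)
    if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
        raise InvalidParameterError("probability map values must lie in [0, 1]")
    return LabelMask((v >= threshold).astype(np.int32), prob, kind)  # type: ignore[arg-type]
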