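"""Volumetric data model, geometry handling, and the MR preprocessing chain.

The preprocessing applied before tumor segmentation follows the standard
contrast-enhanced MR pipeline used by patch-wise CNS segmentation models:
isotropic resampling (default 0.75 mm), optional skull-stripping with a
brain mask, clipping of the 0.05% highest intensities, and min-max
normalization to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidInputError, InvalidParameterError

__all__ = [
    "VolumetricImage",
    "LabelMask",
    "PreprocessingConfig",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "resample_to_isotropic",
    "clip_and_normalize",
    "apply_brain_mask",
    "mask_volume_ml",
    "preprocess",
]

MaskKind = Literal["tumor", "brain", "parcellation"]

#: tolerance of the annotation-to-scan geometry matching rule (shape must be
#: exact; spacing/origin in mm and direction cosines within this bound)
GEOMETRY_ATOL = 1e-3


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise InvalidParameterError(f"direction must be 3x3, got {d.shape}")
    if not np.allclose(d @ d.T, np.eye(3), atol=1e-6):
        raise InvalidParameterError("direction matrix must be orthonormal")
    return d


@dataclass(frozen=True)
class VolumetricImage:
    """A 3D scalar grid with physical geometry.

    Attributes
    ----------
    voxels : np.ndarray
        Rank-3 scalar array indexed (i, j, k).
    spacing : tuple of float
        Voxel size in mm along each index axis; strictly positive.
    origin : tuple of float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    direction : np.ndarray
        Orthonormal 3x3 matrix mapping index axes to physical axes.
        Internally everything is kept in RAS orientation (identity
        direction) after loading, which makes left/right logic well
        defined downstream.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise InvalidParameterError(f"voxel array must be rank 3, got rank {v.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise InvalidParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", _as_direction(self.direction))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->physical affine (voxel centres)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin)
        inv = np.diag([1.0 / s for s in self.spacing]) @ self.direction.T
        return pts @ inv.T

    def with_voxels(self, voxels: np.ndarray) -> "VolumetricImage":
        return dataclasses.replace(self, voxels=voxels)

    def same_geometry(self, other: "VolumetricImage", atol: float = GEOMETRY_ATOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


@dataclass(frozen=True)
class LabelMask:
    """Integer labels living on a :class:`VolumetricImage` grid."""

    labels: np.ndarray
    grid: VolumetricImage
    kind: MaskKind = "tumor"

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise InvalidParameterError("label array must be rank 3")
        if lab.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {lab.shape} differs from its grid shape {self.grid.shape}"
            )
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise InvalidParameterError("labels must be integers")
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise InvalidParameterError("labels must be non-negative")
        if self.kind in ("tumor", "brain") and lab.max(initial=0) > 1:
            raise InvalidParameterError(f"{self.kind} mask must be binary")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def with_labels(self, labels: np.ndarray, kind: MaskKind | None = None) -> "LabelMask":
        return LabelMask(labels, self.grid, kind or self.kind)


@dataclass(frozen=True)
class PreprocessingConfig:
    """Preprocessing policy for MR scans before segmentation.

    Defaults mirror the standard pipeline: 0.75 mm isotropic resampling,
    clipping of the 0.05% highest intensities, scaling to [0, 1].
    ``clip_on_brain_only`` restricts the clipping quantile to brain-masked
    voxels; by default statistics are computed over the whole volume.
    """

    target_spacing_mm: float = 0.75
    clip_upper_fraction: float = 0.0005
    skull_strip: bool = True
    normalization_range: tuple[float, float] = (0.0, 1.0)
    clip_on_brain_only: bool = False

    def __post_init__(self):
        if not (0 <= self.clip_upper_fraction < 1):
            raise InvalidParameterError("clip_upper_fraction must be in [0, 1)")
        if self.target_spacing_mm <= 0:
            raise InvalidParameterError("target_spacing_mm must be > 0")
        lo, hi = self.normalization_range
        if not lo < hi:
            raise InvalidParameterError("normalization_range must be increasing")


# ---------------------------------------------------------------------------
# I/O — NIfTI as the canonical on-disk format; .mhd/.nrrd readable via
# SimpleITK and converted on load.
# ---------------------------------------------------------------------------

def _from_nibabel(img: nib.Nifti1Image) -> VolumetricImage:
    img = nib.as_closest_canonical(img)  # RAS canonical orientation
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    aff = img.affine
    m = aff[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    direction = m / spacing
    return VolumetricImage(data, tuple(spacing), tuple(aff[:3, 3]), direction)


def load_image(path: str | Path) -> VolumetricImage:
    """Read a volume (.nii/.nii.gz natively; .mhd/.nrrd via SimpleITK)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _from_nibabel(nib.load(str(path)))
    import SimpleITK as sitk  # only needed for non-NIfTI inputs

    itk = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(itk)  # (z, y, x)
    arr = np.transpose(arr, (2, 1, 0)).astype(np.float64)
    spacing = itk.GetSpacing()
    origin = np.array(itk.GetOrigin())
    direction = np.array(itk.GetDirection()).reshape(3, 3)
    # ITK uses LPS physical coordinates; convert to RAS (flip x and y).
    flip = np.diag([-1.0, -1.0, 1.0])
    aff = np.eye(4)
    aff[:3, :3] = flip @ direction @ np.diag(spacing)
    aff[:3, 3] = flip @ origin
    return _from_nibabel(nib.Nifti1Image(arr, aff))


def save_image(image: VolumetricImage, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(image.voxels, dtype=np.float32), image.affine), str(path))
    return path


def load_mask(path: str | Path, kind: MaskKind = "tumor") -> LabelMask:
    img = load_image(path)
    return LabelMask(np.round(img.voxels).astype(np.int32), img.with_voxels(img.voxels), kind)


def save_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(mask.labels.astype(np.uint16), mask.grid.affine), str(path)
    )
    return path


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def resample_to_isotropic(
    image: VolumetricImage,
    target_spacing_mm: float = 0.75,
    interpolation: Literal["linear", "nearest"] = "linear",
) -> VolumetricImage:
    """Resample a volume onto an isotropic grid, preserving physical extent.

    Output shape per axis is ``round(shape_i * spacing_i / t)``. Cell-edge
    alignment (``grid_mode``) keeps the physical extent identical up to the
    sub-voxel rounding of the shape.
    """
    t = float(target_spacing_mm)
    if t <= 0:
        raise InvalidParameterError("target spacing must be positive")
    if interpolation not in ("linear", "nearest"):
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")
    old_shape = np.array(image.shape)
    old_spacing = np.array(image.spacing)
    new_shape = np.maximum(1, np.round(old_shape * old_spacing / t).astype(int))
    if tuple(new_shape) == tuple(old_shape) and np.allclose(old_spacing, t):
        return dataclasses.replace(image, spacing=(t, t, t))
    order = 1 if interpolation == "linear" else 0
    out = ndimage.zoom(
        np.asarray(image.voxels, dtype=float),
        zoom=new_shape / old_shape,
        order=order,
        mode="grid-constant",
        grid_mode=True,
        prefilter=False,
    )
    assert out.shape == tuple(new_shape)
    # voxel (0,0,0) centre shifts by half the spacing difference per axis
    shift = image.direction @ ((t - old_spacing) / 2.0)
    new_origin = tuple(np.asarray(image.origin) + shift)
    return VolumetricImage(out, (t, t, t), new_origin, image.direction)


def resample_mask_to_isotropic(mask: LabelMask, target_spacing_mm: float) -> LabelMask:
    """Nearest-neighbour resampling of a label mask; never invents labels."""
    img = VolumetricImage(mask.labels.astype(float), mask.grid.spacing, mask.grid.origin, mask.grid.direction)
    res = resample_to_isotropic(img, target_spacing_mm, interpolation="nearest")
    return LabelMask(np.round(res.voxels).astype(np.int32), res.with_voxels(res.voxels), mask.kind)


def clip_and_normalize(
    image: VolumetricImage,
    clip_upper_fraction: float = 0.0005,
    value_range: tuple[float, float] = (0.0, 1.0),
    stats_mask: np.ndarray | None = None,
) -> VolumetricImage:
    """Clip the highest intensities and min-max scale to ``value_range``.

    Values above the ``1 - clip_upper_fraction`` linear-interpolation
    quantile are set to that quantile, then the volume is affinely mapped so
    min -> low and max -> high. A constant volume maps to all-low.
    ``stats_mask`` optionally restricts the quantile computation (e.g. to
    brain voxels); clipping and scaling still apply to the whole volume.
    """
    if not (0 <= clip_upper_fraction < 1):
        raise InvalidParameterError("clip_upper_fraction must be in [0, 1)")
    low, high = float(value_range[0]), float(value_range[1])
    if not low < high:
        raise InvalidParameterError("range must be increasing")
    v = np.asarray(image.voxels, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("voxel values must be finite (NaN/Inf present)")
    stats = v if stats_mask is None else v[np.asarray(stats_mask, bool)]
    if stats.size == 0:
        raise InvalidInputError("statistics mask selects no voxels")
    if clip_upper_fraction > 0:
        q = float(np.quantile(stats, 1.0 - clip_upper_fraction))
        v = np.minimum(v, q)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        out = np.full_like(v, low)
    else:
        out = low + (v - vmin) * ((high - low) / (vmax - vmin))
    return image.with_voxels(out)


def apply_brain_mask(image: VolumetricImage, brain: LabelMask, background: float = 0.0) -> VolumetricImage:
    """Skull-strip: zero (background) everything outside the brain mask."""
    if brain.kind != "brain":
        raise InvalidParameterError(f"expected a brain mask, got kind={brain.kind!r}")
    if not image.same_geometry(brain.grid):
        raise GeometryError("brain mask geometry does not match the image")
    out = np.where(brain.labels > 0, image.voxels, background)
    return image.with_voxels(out)


def mask_volume_ml(mask: LabelMask) -> float:
    """Foreground volume in millilitres (voxel count x voxel volume / 1000)."""
    if mask.kind not in ("tumor", "brain"):
        raise InvalidParameterError("volume is defined for binary tumor/brain masks")
    return mask.foreground_count() * mask.grid.voxel_volume_mm3 / 1000.0


def preprocess(
    image: VolumetricImage,
    config: PreprocessingConfig = PreprocessingConfig(),
    brain: LabelMask | None = None,
) -> VolumetricImage:
    """Full preprocessing chain: resample, (skull-strip), clip, normalize."""
    out = resample_to_isotropic(image, config.target_spacing_mm, "linear")
    brain_res = None
    if brain is not None:
        brain_res = resample_mask_to_isotropic(brain, config.target_spacing_mm)
    stats_mask = None
    if config.clip_on_brain_only and brain_res is not None:
        stats_mask = brain_res.labels > 0
    out = clip_and_normalize(out, config.clip_upper_fraction, config.normalization_range, stats_mask)
    if config.skull_strip and brain_res is not None:
        out = apply_brain_mask(out, brain_res, background=config.normalization_range[0])
    return out
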