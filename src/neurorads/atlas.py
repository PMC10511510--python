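"""Patient-to-reference registration, mask warping, and region-overlap profiles.

Tumor characteristics are computed in a standard reference space (in
clinical use, the symmetric MNI ICBM2009a template): the patient scan is
registered to the reference, the tumor mask is warped there, and its overlap
against hemisphere masks and named parcellations is profiled. Deformable
registration (e.g. ANTs SyN) is deliberately not reimplemented — the module
defines a transform interface with a moment-matching affine built in and an
``external`` slot for plugging in any backend that produces an affine +
translation in physical coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, GeometryError, InvalidParameterError, RegistrationError
from .image_core import LabelMask, VolumetricImage, load_image, load_mask, save_image, save_mask

__all__ = [
    "SpatialTransform",
    "AtlasBundle",
    "estimate_transform",
    "warp_mask",
    "warp_image",
    "region_overlap_profile",
    "load_atlas",
    "save_atlas",
]


@dataclass(frozen=True)
class SpatialTransform:
    """Affine map from moving physical space to reference physical space.

    ``y = matrix @ x + translation`` (mm). ``kind`` records provenance:
    identity/rigid/affine are internal estimates, ``external`` wraps
    parameters produced by an outside registration backend.
    """

    kind: str = "identity"
    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(m)) < 1e-12:
            raise InvalidParameterError("transform matrix must be invertible")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.matrix.T + self.translation

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.matrix)
        return (np.atleast_2d(points) - self.translation) @ inv.T

    def inverse(self) -> "SpatialTransform":
        inv = np.linalg.inv(self.matrix)
        return SpatialTransform(self.kind, inv, -inv @ self.translation)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "translation_mm": self.translation.tolist(),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SpatialTransform":
        d = json.loads(Path(path).read_text())
        return cls(d["kind"], np.array(d["matrix"]), np.array(d["translation_mm"]))


@dataclass(frozen=True)
class AtlasBundle:
    """Reference template plus hemisphere masks and named parcellations.

    ``hemispheres`` uses label 1 = left, 2 = right. Each parcellation has a
    label table mapping every nonzero label to a structure name.
    """

    reference: VolumetricImage
    hemispheres: LabelMask
    parcellations: Mapping[str, LabelMask]
    label_tables: Mapping[str, Mapping[int, str]]

    LEFT, RIGHT = 1, 2

    def __post_init__(self):
        if not self.hemispheres.grid.same_geometry(self.reference):
            raise GeometryError("hemisphere mask must live on the reference grid")
        for name, parc in self.parcellations.items():
            if not parc.grid.same_geometry(self.reference):
                raise GeometryError(f"parcellation {name!r} not on the reference grid")
            present = set(np.unique(parc.labels)) - {0}
            table = self.label_tables.get(name, {})
            missing = present - set(table)
            if missing:
                raise InvalidParameterError(
                    f"label table for {name!r} misses labels {sorted(missing)}"
                )


def _weighted_moments(image: VolumetricImage) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre of mass (mm) and per-physical-axis intensity-weighted std (mm)."""
    w = np.asarray(image.voxels, dtype=float)
    w = w - w.min()
    total = w.sum()
    if total <= 0:
        raise RegistrationError("degenerate (constant or empty) image")
    idx = np.indices(image.shape).reshape(3, -1).T
    pts = image.index_to_physical(idx)
    wf = w.reshape(-1) / total
    com = wf @ pts
    var = wf @ (pts - com) ** 2
    if np.any(var <= 0):
        raise RegistrationError("image has zero spatial variance along an axis")
    return com, np.sqrt(var), float(total)


def estimate_transform(
    moving: VolumetricImage,
    reference: VolumetricImage,
    method: str = "centered_affine",
) -> SpatialTransform:
    """Estimate a moving->reference transform.

    ``centered_affine`` matches intensity centres of mass and per-axis
    second moments (an axis-aligned scale + translation). ``external`` is a
    plug-in slot: callers supply backend results via
    :class:`SpatialTransform` directly; requesting it here raises.
    """
    if method == "external":
        raise InvalidParameterError(
            "external registration results must be provided as a SpatialTransform"
        )
    if method != "centered_affine":
        raise InvalidParameterError(f"unknown registration method {method!r}")
    com_m, std_m, _ = _weighted_moments(moving)
    com_r, std_r, _ = _weighted_moments(reference)
    scale = std_r / std_m
    matrix = np.diag(scale)
    translation = com_r - matrix @ com_m
    return SpatialTransform("affine", matrix, translation)


def _resample_on_grid(
    values: np.ndarray,
    source: VolumetricImage,
    transform: SpatialTransform,
    reference_grid: VolumetricImage,
    order: int,
) -> np.ndarray:
    """Pull-back resampling of ``values`` (on source grid) onto the reference grid."""
    idx = np.indices(reference_grid.shape).reshape(3, -1).T
    pts_ref = reference_grid.index_to_physical(idx)
    pts_mov = transform.apply_inverse(pts_ref)
    coords = source.physical_to_index(pts_mov).T
    out = ndimage.map_coordinates(
        np.asarray(values, dtype=float), coords, order=order, mode="constant", cval=0.0
    )
    return out.reshape(reference_grid.shape)


def warp_mask(
    mask: LabelMask, transform: SpatialTransform, reference_grid: VolumetricImage
) -> LabelMask:
    """Nearest-neighbour warp of a label mask onto the reference grid."""
    if transform.kind == "identity" and mask.grid.same_geometry(reference_grid):
        return LabelMask(mask.labels.copy(), reference_grid, mask.kind)
    out = _resample_on_grid(mask.labels, mask.grid, transform, reference_grid, order=0)
    return LabelMask(np.round(out).astype(np.int32), reference_grid, mask.kind)


def warp_image(
    image: VolumetricImage, transform: SpatialTransform, reference_grid: VolumetricImage
) -> VolumetricImage:
    """Linear-interpolation warp of a scalar volume onto the reference grid."""
    out = _resample_on_grid(image.voxels, image, transform, reference_grid, order=1)
    return reference_grid.with_voxels(out)


UNLABELED = "unlabeled"


def region_overlap_profile(
    tumor: LabelMask, parcellation: LabelMask, label_table: Mapping[int, str]
) -> dict[str, float]:
    """Percentage of tumor volume inside each named region.

    Includes an ``unlabeled`` bucket for tumor voxels whose parcellation
    label is 0; entries sum to 100 exactly up to rounding of the division.
    """
    if not tumor.grid.same_geometry(parcellation.grid):
        raise GeometryError("tumor and parcellation must share a grid")
    n_tumor = tumor.foreground_count()
    if n_tumor == 0:
        raise EmptyMaskError("cannot profile an empty tumor mask")
    labels_in_tumor = parcellation.labels[tumor.labels > 0]
    counts = np.bincount(labels_in_tumor.reshape(-1))
    profile: dict[str, float] = {
        UNLABELED: float(100.0 * counts[0] / n_tumor) if counts.size else 0.0
    }
    for label, name in sorted(label_table.items()):
        c = counts[label] if label < counts.size else 0
        profile[name] = float(100.0 * c / n_tumor)
    return profile


# ---------------------------------------------------------------------------
# Atlas persistence: one NIfTI per mask + CSV label tables
# ---------------------------------------------------------------------------

def save_atlas(atlas: AtlasBundle, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_image(atlas.reference, directory / "reference.nii.gz")
    save_mask(atlas.hemispheres, directory / "hemispheres.nii.gz")
    for name, parc in atlas.parcellations.items():
        save_mask(parc, directory / f"{name}.nii.gz")
        table = atlas.label_tables[name]
        pd.DataFrame(
            {"label": list(table.keys()), "name": list(table.values())}
        ).to_csv(directory / f"{name}_labels.csv", index=False)
    return directory


def load_atlas(directory: str | Path) -> AtlasBundle:
    directory = Path(directory)
    reference = load_image(directory / "reference.nii.gz")
    hemispheres = load_mask(directory / "hemispheres.nii.gz", kind="parcellation")
    parcellations: dict[str, LabelMask] = {}
    tables: dict[str, dict[int, str]] = {}
    for csv_path in sorted(directory.glob("*_labels.csv")):
        name = csv_path.name[: -len("_labels.csv")]
        parcellations[name] = load_mask(directory / f"{name}.nii.gz", kind="parcellation")
        df = pd.read_csv(csv_path)
        tables[name] = dict(zip(df["label"].astype(int), df["name"].astype(str)))
    return AtlasBundle(reference, hemispheres, parcellations, tables)
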