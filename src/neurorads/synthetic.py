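"""Deterministic synthetic phantoms, tumors, atlases, predictors and cohorts.

Real cohorts of contrast-enhanced MR scans are GDPR-restricted, so every
downstream module is exercised on generated data instead: an ellipsoidal
head phantom with an exactly known brain mask, union-of-ellipsoid
enhancing tumors with closed-form volumes, a toy hemisphere/parcellation
atlas, a voxel-local threshold predictor standing in for trained models,
and multi-timestamp cohort directory trees with a ground-truth manifest.
Everything is seed-deterministic: the same spec yields bit-identical
output. Ellipsoid realism is deliberately not attempted — the phantoms
exist to make every computation checkable against closed forms, not to
look like brains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .image_core import LabelMask, VolumetricImage, save_image, save_mask
from .inference import FunctionPredictor
from .atlas import AtlasBundle, save_atlas
from .reporting import extent_of_resection

__all__ = [
    "PhantomSpec",
    "TumorFocus",
    "TumorSpec",
    "make_head_phantom",
    "make_tumor",
    "make_toy_atlas",
    "make_threshold_predictor",
    "make_synthetic_cohort",
    "ellipsoid_analytic_volume_ml",
    "ellipsoid_grid_volume_ml",
]

# intensity plateaus of the piecewise-constant phantom (pre-normalization)
HEAD_INTENSITY = 0.2
BRAIN_INTENSITY = 0.55
DEFAULT_TUMOR_INTENSITY_OFFSET = 0.35


@dataclass(frozen=True)
class PhantomSpec:
    """Head-phantom recipe; identical specs produce bit-identical phantoms."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    brain_radius_fraction: float = 0.38
    noise_sd: float = 0.01


@dataclass(frozen=True)
class TumorFocus:
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    intensity_offset: float = DEFAULT_TUMOR_INTENSITY_OFFSET


@dataclass(frozen=True)
class TumorSpec:
    foci: tuple[TumorFocus, ...]
    seed: int = 0


def ellipsoid_analytic_volume_ml(radii_mm: Sequence[float]) -> float:
    """Closed-form ellipsoid volume 4/3 π a b c, in ml."""
    a, b, c = radii_mm
    return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def _inside_ellipsoid(grid: VolumetricImage, center_mm, radii_mm) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=float)
    pts = np.stack(
        [idx[a] * grid.spacing[a] + grid.origin[a] for a in range(3)]
    )  # physical coords per axis (identity direction)
    r = [(pts[a] - center_mm[a]) / radii_mm[a] for a in range(3)]
    return r[0] ** 2 + r[1] ** 2 + r[2] ** 2 <= 1.0


def ellipsoid_grid_volume_ml(grid: VolumetricImage, center_mm, radii_mm) -> float:
    """Volume of the voxelized ellipsoid: count of grid centres inside, in ml.

    Re-evaluates the inside-ellipsoid predicate on the grid; used for
    manifest ground truth without reading back any generated mask array.
    """
    return int(_inside_ellipsoid(grid, center_mm, radii_mm).sum()) * grid.voxel_volume_mm3 / 1000.0


def _brain_geometry(spec: PhantomSpec):
    shape = np.asarray(spec.shape, dtype=float)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    extent = shape * spacing
    center = (shape - 1) * spacing / 2.0
    brain_radii = spec.brain_radius_fraction * extent
    head_radii = np.minimum(1.25 * brain_radii, (extent - spacing) / 2.0)
    return center, brain_radii, head_radii


def make_head_phantom(spec: PhantomSpec = PhantomSpec()) -> tuple[VolumetricImage, LabelMask]:
    """Ellipsoidal bright brain inside a darker head, plus the exact brain mask."""
    if any(s < 8 for s in spec.shape):
        raise InvalidParameterError("phantom shape must be at least 8 voxels per axis")
    grid = VolumetricImage(
        np.zeros(spec.shape, dtype=float), spec.spacing_mm, (0.0, 0.0, 0.0)
    )
    center, brain_radii, head_radii = _brain_geometry(spec)
    head = _inside_ellipsoid(grid, center, head_radii)
    brain = _inside_ellipsoid(grid, center, brain_radii)
    vox = np.zeros(spec.shape, dtype=float)
    vox[head] = HEAD_INTENSITY
    vox[brain] = BRAIN_INTENSITY
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    image = grid.with_voxels(vox)
    mask = LabelMask(brain.astype(np.int32), image, "brain")
    return image, mask


def make_tumor(
    spec: TumorSpec, image: VolumetricImage, brain: LabelMask
) -> tuple[LabelMask, VolumetricImage, list[float]]:
    """Union-of-ellipsoids enhancing lesion on a phantom.

    Returns the tumor mask, the image with intensities raised inside the
    foci (emulating gadolinium enhancement), and the closed-form per-focus
    volumes in ml. Every focus must lie inside the brain mask.
    """
    union = np.zeros(image.shape, dtype=bool)
    analytic_volumes = []
    for focus in spec.foci:
        inside = _inside_ellipsoid(image, focus.center_mm, focus.radii_mm)
        if not inside.any():
            raise InvalidInputError(f"focus at {focus.center_mm} covers no voxel")
        if np.any(inside & (brain.labels == 0)):
            raise InvalidInputError(f"focus at {focus.center_mm} extends outside the brain")
        union |= inside
        analytic_volumes.append(ellipsoid_analytic_volume_ml(focus.radii_mm))
    vox = np.array(image.voxels, dtype=float)
    for focus in spec.foci:
        inside = _inside_ellipsoid(image, focus.center_mm, focus.radii_mm)
        vox[inside] = BRAIN_INTENSITY + focus.intensity_offset
    mask = LabelMask(union.astype(np.int32), image, "tumor")
    return mask, image.with_voxels(vox), analytic_volumes


def make_toy_atlas(grid: VolumetricImage, n_regions: int = 4, seed: int = 0,
                   brain: LabelMask | None = None) -> AtlasBundle:
    """Toy reference bundle on a phantom grid.

    Hemispheres split the brain at the central physical plane of the first
    (left-right) axis; the parcellation slices the brain into ``n_regions``
    contiguous slabs along the last axis, with a generated label table.
    """
    if n_regions < 1:
        raise InvalidParameterError("need at least one region")
    if brain is None:
        brain_arr = np.ones(grid.shape, dtype=bool)
    else:
        brain_arr = brain.labels > 0
    hemi = np.zeros(grid.shape, dtype=np.int32)
    mid = grid.shape[0] / 2.0
    i = np.arange(grid.shape[0])[:, None, None]
    hemi_full = np.where(i < mid, AtlasBundle.LEFT, AtlasBundle.RIGHT)
    hemi = np.where(brain_arr, hemi_full, 0).astype(np.int32)
    # contiguous slabs along the last axis, restricted to the brain
    k = np.arange(grid.shape[2])
    edges = np.linspace(0, grid.shape[2], n_regions + 1)
    slab_of_k = np.clip(np.searchsorted(edges, k, side="right"), 1, n_regions)
    parc_full = np.broadcast_to(slab_of_k[None, None, :], grid.shape)
    parc = np.where(brain_arr, parc_full, 0).astype(np.int32)
    table = {r: f"region_{r}" for r in range(1, n_regions + 1)}
    reference = grid.with_voxels(np.asarray(grid.voxels, dtype=float))
    return AtlasBundle(
        reference=reference,
        hemispheres=LabelMask(hemi, reference, "parcellation"),
        parcellations={"toy_parcellation": LabelMask(parc, reference, "parcellation")},
        label_tables={"toy_parcellation": table},
    )


def make_threshold_predictor(threshold: float = 0.75, patch_shape=(160, 160, 160)) -> FunctionPredictor:
    """Voxel-local predictor: probability 1 where intensity > threshold.

    Being purely voxel-local it must give identical results patch-wise and
    whole-volume, which is the central stitching check; on a phantom whose
    tumor plateau exceeds the threshold it recovers the tumor mask exactly.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError("threshold must lie in [0, 1]")
    return FunctionPredictor(
        fn=lambda patch: (np.asarray(patch) > threshold).astype(float),
        input_patch_shape=tuple(patch_shape),
    )


def _random_focus(rng: np.random.Generator, center, brain_radii, radius_range) -> TumorFocus:
    # containment guarantee in brain-normalized coordinates: any point of the
    # focus has norm <= ||c/R|| + max(r_i/R_i), so keeping that sum below 1
    # keeps the whole ellipsoid inside the brain ellipsoid
    radii = rng.uniform(*radius_range, size=3)
    max_norm = max(0.0, 0.9 * (1.0 - float(np.max(radii / brain_radii))))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    offset = direction * rng.uniform(0.0, max_norm) * brain_radii
    return TumorFocus(tuple(center + offset), tuple(radii))


def make_synthetic_cohort(
    n_patients: int,
    seed: int,
    out_dir: str | Path,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    multifocal_fraction: float = 0.3,
    complete_resection_fraction: float = 0.25,
    noise_sd: float = 0.01,
) -> dict:
    """Write a multi-timestamp cohort tree and its ground-truth manifest.

    Layout: ``<out_dir>/<patient_id>/T0`` (preoperative) and ``T1``
    (postoperative), each holding ``t1c.nii.gz``, ``tumor_mask.nii.gz``
    and ``brain_mask.nii.gz``. The postoperative tumor is the preoperative
    main focus shrunk by a random factor (or removed entirely for complete
    resections). The manifest records, per patient, the closed-form
    (``analytic``) and grid-predicate (``grid``) volumes, focus count, and
    the EOR implied by the grid volumes — all derived from the specs, never
    read back from the written voxel arrays.
    """
    if n_patients < 1:
        raise InvalidParameterError("need at least one patient")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "patients": {}}
    for p in range(n_patients):
        pid = f"patient_{p:03d}"
        prng = np.random.default_rng(master.integers(0, 2**31 - 1))
        pspec = PhantomSpec(shape=shape, spacing_mm=spacing_mm,
                            seed=int(prng.integers(0, 2**31 - 1)), noise_sd=noise_sd)
        image, brain = make_head_phantom(pspec)
        center, brain_radii, _ = _brain_geometry(pspec)
        min_r = 3.2 * max(spacing_mm)
        max_r = 0.45 * float(brain_radii.min())
        foci = [_random_focus(prng, center, brain_radii, (min_r, max(max_r, min_r + 1e-6)))]
        if prng.uniform() < multifocal_fraction:
            # satellite must stay disjoint from the main focus (with a gap of
            # more than one voxel) so component labelling sees two foci
            main = foci[0]
            for _ in range(50):
                sat = _random_focus(prng, center, brain_radii, (min_r, max(0.6 * max_r, min_r + 1e-6)))
                gap = np.linalg.norm(np.array(sat.center_mm) - np.array(main.center_mm)) - (
                    max(sat.radii_mm) + max(main.radii_mm)
                )
                if gap > 2.0 * max(spacing_mm):
                    foci.append(sat)
                    break
        pre_spec = TumorSpec(foci=tuple(foci), seed=pspec.seed)
        pre_mask, pre_image, analytic_vols = make_tumor(pre_spec, image, brain)

        # postoperative: shrink the main focus, drop satellites (resected)
        complete = prng.uniform() < complete_resection_fraction
        if complete:
            post_foci: tuple[TumorFocus, ...] = ()
            post_mask = LabelMask(np.zeros(shape, dtype=np.int32), image, "tumor")
            post_image = image
            post_analytic: list[float] = []
        else:
            shrink = float(prng.uniform(0.25, 0.6))
            main = foci[0]
            residual = TumorFocus(
                main.center_mm,
                tuple(max(r * shrink, 1.05 * max(spacing_mm)) for r in main.radii_mm),
                main.intensity_offset,
            )
            post_foci = (residual,)
            post_mask, post_image, post_analytic = make_tumor(
                TumorSpec(foci=post_foci, seed=pspec.seed), image, brain
            )

        grid_pre = (
            int(np.logical_or.reduce([
                _inside_ellipsoid(image, f.center_mm, f.radii_mm) for f in foci
            ]).sum()) * image.voxel_volume_mm3 / 1000.0
        )
        grid_post = sum(
            ellipsoid_grid_volume_ml(image, f.center_mm, f.radii_mm) for f in post_foci
        )
        for label, img, tmask in (("T0", pre_image, pre_mask), ("T1", post_image, post_mask)):
            tdir = out_dir / pid / label
            tdir.mkdir(parents=True, exist_ok=True)
            save_image(img, tdir / "t1c.nii.gz")
            save_mask(tmask, tdir / "tumor_mask.nii.gz")
            save_mask(brain, tdir / "brain_mask.nii.gz")
        manifest["patients"][pid] = {
            "n_foci_preop": len(foci),
            "multifocal": len(foci) >= 2,
            "analytic_preop_ml": [float(v) for v in analytic_vols],
            "analytic_postop_ml": [float(v) for v in post_analytic],
            "grid_preop_ml": float(grid_pre),
            "grid_postop_ml": float(grid_post),
            "eor_pct": float(extent_of_resection(grid_pre, grid_post)),
            "complete_resection": bool(complete),
        }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
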