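"""Standardized pre- and postoperative tumor reports.

The preoperative report characterizes the tumor in reference space: volume
(in both patient and reference space, since affine registration changes
volume), laterality with midline-crossing, multifocality with per-focus
records, and one location profile per atlas parcellation. The postoperative
report compares pre- and postoperative volumes into an extent of resection
(EOR) and a guideline-style resection class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .atlas import AtlasBundle, region_overlap_profile
from .errors import ConfigError, EmptyMaskError, GeometryError, InvalidInputError, InvalidParameterError
from .image_core import LabelMask, mask_volume_ml

__all__ = [
    "FocusRecord",
    "LateralityRecord",
    "StandardizedReport",
    "ReportConfig",
    "laterality_assessment",
    "extract_foci",
    "extent_of_resection",
    "classify_resection_extent",
    "assemble_preop_report",
    "assemble_postop_report",
]

CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class FocusRecord:
    """One connected tumor component, ordered by descending volume."""

    focus_id: int
    volume_ml: float
    centroid_mm: tuple[float, float, float]


@dataclass(frozen=True)
class LateralityRecord:
    left_pct: float
    right_pct: float
    midline_crossing: bool
    dominant: Literal["left", "right"]


@dataclass(frozen=True)
class ReportConfig:
    """Tunable reporting thresholds.

    Resection classes follow RANO-resect-style residual-volume bands and
    are fully configurable; ``resection_bands`` maps class name to the
    inclusive upper residual bound in ml, in increasing order, with the
    last class unbounded.
    """

    min_focus_ml: float = 0.1
    connectivity: Literal[6, 18, 26] = 26
    midline_crossing_threshold_pct: float = 5.0
    resection_bands: tuple[tuple[str, float], ...] = (
        ("complete", 0.0),
        ("near-total", 1.0),
        ("subtotal", 5.0),
    )
    final_resection_class: str = "partial"
    profile_decimals: int = 2

    def __post_init__(self):
        bounds = [b for _, b in self.resection_bands]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or (bounds and bounds[0] < 0):
            raise ConfigError("resection bands must have increasing non-negative bounds")
        if self.connectivity not in CONNECTIVITY_STRUCTURES:
            raise ConfigError("connectivity must be one of 6, 18, 26")


@dataclass(frozen=True)
class StandardizedReport:
    """Hierarchical record of tumor features for one patient and phase."""

    phase: Literal["preoperative", "postoperative"]
    volumes: Mapping[str, float]
    laterality: LateralityRecord | None = None
    foci: tuple[FocusRecord, ...] = ()
    multifocal: bool = False
    nearest_satellite_distance_mm: float | None = None
    profiles: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    eor_pct: float | None = None
    resection_class: str | None = None
    tumor_growth: bool = False
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.laterality is not None:
            total = self.laterality.left_pct + self.laterality.right_pct
            if abs(total - 100.0) > 1e-6:
                raise InvalidInputError(f"laterality percentages sum to {total}, not 100")
        if self.eor_pct is not None and self.eor_pct > 100.0:
            raise InvalidInputError("extent of resection cannot exceed 100%")
        if self.multifocal != (len(self.foci) >= 2):
            raise InvalidInputError("multifocal flag inconsistent with focus count")

    def to_dict(self) -> dict:
        d: dict = {"phase": self.phase, "volumes": dict(self.volumes)}
        if self.laterality is not None:
            d["laterality"] = {
                "left_pct": self.laterality.left_pct,
                "right_pct": self.laterality.right_pct,
                "midline_crossing": self.laterality.midline_crossing,
                "dominant": self.laterality.dominant,
            }
        d["foci"] = [
            {"focus_id": f.focus_id, "volume_ml": f.volume_ml, "centroid_mm": list(f.centroid_mm)}
            for f in self.foci
        ]
        d["multifocal"] = self.multifocal
        if self.nearest_satellite_distance_mm is not None:
            d["nearest_satellite_distance_mm"] = self.nearest_satellite_distance_mm
        if self.profiles:
            d["profiles"] = {k: dict(v) for k, v in self.profiles.items()}
        if self.eor_pct is not None:
            d["eor_pct"] = self.eor_pct
        if self.resection_class is not None:
            d["resection_class"] = self.resection_class
        if self.phase == "postoperative":
            d["tumor_growth"] = self.tumor_growth
        d["provenance"] = dict(self.provenance)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StandardizedReport":
        lat = None
        if "laterality" in d:
            lat = LateralityRecord(
                d["laterality"]["left_pct"],
                d["laterality"]["right_pct"],
                d["laterality"]["midline_crossing"],
                d["laterality"]["dominant"],
            )
        foci = tuple(
            FocusRecord(f["focus_id"], f["volume_ml"], tuple(f["centroid_mm"]))
            for f in d.get("foci", [])
        )
        return cls(
            phase=d["phase"],
            volumes=dict(d["volumes"]),
            laterality=lat,
            foci=foci,
            multifocal=d.get("multifocal", False),
            nearest_satellite_distance_mm=d.get("nearest_satellite_distance_mm"),
            profiles={k: dict(v) for k, v in d.get("profiles", {}).items()},
            eor_pct=d.get("eor_pct"),
            resection_class=d.get("resection_class"),
            tumor_growth=d.get("tumor_growth", False),
            provenance=dict(d.get("provenance", {})),
        )


def laterality_assessment(
    tumor_ref: LabelMask,
    hemispheres: LabelMask,
    crossing_threshold_pct: float = 5.0,
) -> LateralityRecord:
    """Left/right split of tumor volume against hemisphere labels.

    Percentages are computed over tumor voxels carrying a hemisphere label,
    so left + right = 100 exactly; voxels outside both hemisphere labels
    (e.g. in the interhemispheric gap after warping) are ignored. Midline
    crossing is flagged when both sides exceed the threshold; dominance
    ties break to left by convention.
    """
    if not tumor_ref.grid.same_geometry(hemispheres.grid):
        raise GeometryError("tumor and hemisphere masks must share a grid")
    n = tumor_ref.foreground_count()
    if n == 0:
        raise EmptyMaskError("cannot assess laterality of an empty tumor")
    hemi = hemispheres.labels[tumor_ref.labels > 0]
    n_left = int(np.count_nonzero(hemi == AtlasBundle.LEFT))
    n_right = int(np.count_nonzero(hemi == AtlasBundle.RIGHT))
    denom = n_left + n_right
    if denom == 0:
        # tumor entirely outside hemisphere labels: undecidable, report 50/50
        left = right = 50.0
    else:
        left = 100.0 * n_left / denom
        right = 100.0 * n_right / denom
    crossing = left > crossing_threshold_pct and right > crossing_threshold_pct
    dominant = "left" if left >= right else "right"
    return LateralityRecord(left, right, crossing, dominant)


def extract_foci(
    tumor: LabelMask,
    connectivity: Literal[6, 18, 26] = 26,
    min_focus_ml: float = 0.1,
) -> list[FocusRecord]:
    """Connected tumor components above the minimum reportable volume.

    Components smaller than ``min_focus_ml`` are dropped from the focus list
    (they still count toward total volume elsewhere). Foci are sorted by
    descending volume and renumbered from 1.
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise InvalidParameterError("connectivity must be 6, 18 or 26")
    binary = tumor.labels > 0
    labelled, n = ndimage.label(binary, structure=CONNECTIVITY_STRUCTURES[connectivity])
    if n == 0:
        return []
    counts = np.bincount(labelled.reshape(-1))[1:]
    vox_ml = tumor.grid.voxel_volume_mm3 / 1000.0
    centroids = ndimage.center_of_mass(binary, labelled, index=range(1, n + 1))
    records = []
    for comp, (count, centroid) in enumerate(zip(counts, centroids), start=1):
        vol = count * vox_ml
        if vol < min_focus_ml:
            continue
        c_mm = tumor.grid.index_to_physical(np.array(centroid))[0]
        records.append((vol, tuple(float(x) for x in c_mm)))
    records.sort(key=lambda r: -r[0])
    return [
        FocusRecord(i + 1, vol, centroid) for i, (vol, centroid) in enumerate(records)
    ]


def extent_of_resection(preop_ml: float, postop_ml: float) -> float:
    """EOR = 100 x (V_pre - V_post) / V_pre; negative values indicate growth."""
    if preop_ml <= 0:
        raise InvalidInputError("preoperative volume must be positive")
    if postop_ml < 0:
        raise InvalidInputError("postoperative volume cannot be negative")
    return 100.0 * (preop_ml - postop_ml) / preop_ml


def classify_resection_extent(
    residual_ml: float, eor_pct: float | None = None, config: ReportConfig = ReportConfig()
) -> str:
    """Map residual tumor volume onto the configured resection classes."""
    if residual_ml < 0:
        raise InvalidInputError("residual volume cannot be negative")
    for name, upper in config.resection_bands:
        if residual_ml <= upper:
            return name
    return config.final_resection_class


def _nearest_satellite_distance(foci: Sequence[FocusRecord]) -> float | None:
    """Distance (mm) from the largest focus to its nearest other focus."""
    if len(foci) < 2:
        return None
    main = np.array(foci[0].centroid_mm)
    dists = [np.linalg.norm(np.array(f.centroid_mm) - main) for f in foci[1:]]
    return float(min(dists))


def assemble_preop_report(
    tumor_patient_space: LabelMask,
    tumor_ref_space: LabelMask,
    atlas: AtlasBundle,
    config: ReportConfig = ReportConfig(),
    provenance: Mapping[str, str] | None = None,
) -> StandardizedReport:
    """Compose the full preoperative standardized report."""
    if tumor_patient_space.foreground_count() == 0:
        raise EmptyMaskError("preoperative tumor mask is empty")
    if tumor_ref_space.foreground_count() == 0:
        raise EmptyMaskError("reference-space tumor mask is empty")
    volumes = {
        "patient_space_ml": mask_volume_ml(tumor_patient_space),
        "reference_space_ml": mask_volume_ml(tumor_ref_space),
    }
    lat = laterality_assessment(
        tumor_ref_space, atlas.hemispheres, config.midline_crossing_threshold_pct
    )
    foci = extract_foci(tumor_ref_space, config.connectivity, config.min_focus_ml)
    profiles = {
        name: {
            k: round(v, config.profile_decimals)
            for k, v in region_overlap_profile(
                tumor_ref_space, parc, atlas.label_tables[name]
            ).items()
        }
        for name, parc in sorted(atlas.parcellations.items())
    }
    return StandardizedReport(
        phase="preoperative",
        volumes=volumes,
        laterality=lat,
        foci=tuple(foci),
        multifocal=len(foci) >= 2,
        nearest_satellite_distance_mm=_nearest_satellite_distance(foci),
        profiles=profiles,
        provenance=dict(provenance or {}),
    )


def assemble_postop_report(
    preop_tumor: LabelMask,
    postop_tumor: LabelMask,
    config: ReportConfig = ReportConfig(),
    provenance: Mapping[str, str] | None = None,
) -> StandardizedReport:
    """Compose the postoperative report: volumes, EOR, resection class.

    Pre- and postoperative masks may live on different native grids; each
    volume is computed on its own grid.
    """
    preop_ml = mask_volume_ml(preop_tumor)
    if preop_ml <= 0:
        raise InvalidInputError("preoperative tumor mask is empty")
    postop_ml = mask_volume_ml(postop_tumor)
    eor = extent_of_resection(preop_ml, postop_ml)
    growth = eor < 0
    return StandardizedReport(
        phase="postoperative",
        volumes={"preop_ml": preop_ml, "postop_ml": postop_ml},
        eor_pct=min(eor, 100.0),
        resection_class=classify_resection_extent(postop_ml, eor, config),
        tumor_growth=growth,
        provenance=dict(provenance or {}),
    )
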