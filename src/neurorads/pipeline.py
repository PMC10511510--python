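"""Patient/cohort orchestration: data import, configuration, runs, serialization.

A patient folder either contains timestamp subfolders (``T0``, ``T1``, ...,
mapped in ascending order — preoperative first, postoperative after) or is
flat (mapped to a single timestamp). Annotation files are recognised by
name (``*mask*`` / ``*label*``) and auto-linked to the unique
geometry-matching image; ambiguity is an error rather than a guess.
Standardized reports are written as .json (canonical nested form), .csv
(flattened key/value) and .txt (human-readable).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .atlas import AtlasBundle, estimate_transform, load_atlas, warp_mask
from .errors import (
    ConfigError,
    GeometryError,
    InvalidInputError,
    NeuroradsError,
)
from .evaluation import (
    CohortMetricsTable,
    DetectionRule,
    evaluate_patient,
    stratify_by_volume,
)
from .image_core import (
    LabelMask,
    PreprocessingConfig,
    VolumetricImage,
    load_image,
    load_mask,
    preprocess,
    save_mask,
)
from .inference import plan_patch_grid, predict_downsampled, predict_patchwise, binarize_probability
from .reporting import ReportConfig, StandardizedReport, assemble_postop_report, assemble_preop_report
from .synthetic import make_threshold_predictor

__all__ = [
    "PatientRecord",
    "Timestamp",
    "RunConfig",
    "load_patient_record",
    "serialize_report",
    "run_single_patient",
    "run_batch",
]

logger = logging.getLogger("neurorads")

MASK_PATTERN = re.compile(r"(mask|label)", re.IGNORECASE)
IMAGE_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".nrrd")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class PreprocessingSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_spacing_mm: float = 0.75
    clip_upper_fraction: float = 0.0005
    skull_strip: bool = True
    normalization_low: float = 0.0
    normalization_high: float = 1.0
    clip_on_brain_only: bool = False

    def to_config(self) -> PreprocessingConfig:
        return PreprocessingConfig(
            target_spacing_mm=self.target_spacing_mm,
            clip_upper_fraction=self.clip_upper_fraction,
            skull_strip=self.skull_strip,
            normalization_range=(self.normalization_low, self.normalization_high),
            clip_on_brain_only=self.clip_on_brain_only,
        )


class InferenceSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    patch_shape: tuple[int, int, int] = (160, 160, 160)
    min_overlap_fraction: float = 0.0
    fusion: Literal["mean", "max"] = "mean"
    binarization_threshold: float = 0.5
    predictor: Literal["threshold"] = "threshold"
    predictor_threshold: float = 0.75
    brain_predictor_threshold: float = 0.25
    brain_working_shape: tuple[int, int, int] = (128, 128, 128)


class ThresholdSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_focus_ml: float = 0.1
    connectivity: Literal[6, 18, 26] = 26
    midline_crossing_threshold_pct: float = 5.0
    detection_min_dice_pct: float = 0.0
    volume_cutoff_ml: float = 2.0

    def to_report_config(self) -> ReportConfig:
        return ReportConfig(
            min_focus_ml=self.min_focus_ml,
            connectivity=self.connectivity,
            midline_crossing_threshold_pct=self.midline_crossing_threshold_pct,
        )


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    task: Literal["segment", "report_preop", "report_postop", "evaluate"] = "report_preop"
    preprocessing: PreprocessingSettings = Field(default_factory=PreprocessingSettings)
    inference: InferenceSettings = Field(default_factory=InferenceSettings)
    thresholds: ThresholdSettings = Field(default_factory=ThresholdSettings)
    atlas_path: str | None = None
    skip_segmentation: bool = False
    formats: tuple[str, ...] = ("json", "csv", "txt")
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        try:
            return cls.model_validate(json.loads(Path(path).read_text()))
        except Exception as exc:  # pydantic ValidationError or JSON error
            raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Patient data model and import
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Timestamp:
    label: str
    images: tuple[Path, ...]
    masks: tuple[tuple[Path, Path, str], ...]  # (mask_path, parent_image, kind)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    timestamps: tuple[Timestamp, ...]
    root: Path


def _is_image_file(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith((".nii", ".nii.gz", ".mhd", ".nrrd"))


def _mask_kind(path: Path) -> str:
    return "brain" if "brain" in path.name.lower() else "tumor"


def _link_masks(folder: Path) -> tuple[tuple[Path, ...], tuple[tuple[Path, Path, str], ...]]:
    files = sorted(p for p in folder.iterdir() if p.is_file() and _is_image_file(p))
    image_paths = [p for p in files if not MASK_PATTERN.search(p.name)]
    mask_paths = [p for p in files if MASK_PATTERN.search(p.name)]
    images = {p: load_image(p) for p in image_paths}
    links = []
    for mpath in mask_paths:
        mask = load_mask(mpath)
        parents = [p for p, img in images.items() if img.same_geometry(mask.grid)]
        if len(parents) == 0:
            raise GeometryError(
                f"annotation {mpath.name} matches no image in {folder} "
                "(shape/spacing/orientation must match the parent scan)"
            )
        if len(parents) > 1:
            raise InvalidInputError(
                f"annotation {mpath.name} matches several images in {folder}; "
                "explicit parent mapping required"
            )
        links.append((mpath, parents[0], _mask_kind(mpath)))
    return tuple(image_paths), tuple(links)


def load_patient_record(folder_path: str | Path) -> PatientRecord:
    """Map a patient folder onto timestamps with linked annotations."""
    folder = Path(folder_path)
    if not folder.is_dir():
        raise InvalidInputError(f"patient folder {folder} does not exist")
    subdirs = sorted(d for d in folder.iterdir() if d.is_dir())
    timestamps = []
    if subdirs:
        for d in subdirs:
            images, masks = _link_masks(d)
            if images or masks:
                timestamps.append(Timestamp(d.name, images, masks))
    else:
        images, masks = _link_masks(folder)
        if images or masks:
            timestamps.append(Timestamp("T0", images, masks))
    if not timestamps:
        raise InvalidInputError(f"no volumes found under {folder}")
    return PatientRecord(folder.name, tuple(timestamps), folder)


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _flatten(d, prefix="") -> dict[str, object]:
    flat: dict[str, object] = {}
    if isinstance(d, dict):
        for k, v in d.items():
            flat.update(_flatten(v, f"{prefix}{k}."))
    elif isinstance(d, (list, tuple)):
        for i, v in enumerate(d):
            flat.update(_flatten(v, f"{prefix}{i}."))
    else:
        flat[prefix.rstrip(".")] = d
    return flat


def _to_txt(report: StandardizedReport) -> str:
    lines = [f"Standardized {report.phase} report", "=" * 34]
    for key, value in _flatten(report.to_dict()).items():
        lines.append(f"{key:45s} {value}")
    return "\n".join(lines) + "\n"


def serialize_report(
    report: StandardizedReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("json", "csv", "txt"),
    stem: str = "report",
) -> list[Path]:
    """Write the report in the requested formats; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = set(formats) - {"json", "csv", "txt"}
    if unknown:
        raise ConfigError(f"unknown report formats: {sorted(unknown)}")
    if not formats:
        logger.warning("no report formats requested; nothing written")
        return []
    written = []
    d = report.to_dict()
    if "json" in formats:
        p = out_dir / f"{stem}.json"
        p.write_text(json.dumps(d, indent=2, sort_keys=True))
        written.append(p)
    if "csv" in formats:
        p = out_dir / f"{stem}.csv"
        flat = _flatten(d)
        pd.DataFrame({"key": list(flat.keys()), "value": list(flat.values())}).to_csv(
            p, index=False
        )
        written.append(p)
    if "txt" in formats:
        p = out_dir / f"{stem}.txt"
        p.write_text(_to_txt(report))
        written.append(p)
    for p in written:
        logger.info("wrote %s", p)
    return written


# ---------------------------------------------------------------------------
# Single-patient and batch runs
# ---------------------------------------------------------------------------

def _segment_timestamp(
    ts: Timestamp, config: RunConfig
) -> tuple[VolumetricImage, LabelMask, LabelMask | None]:
    """Preprocess the timestamp's scan and obtain its tumor mask.

    Returns (preprocessed image, tumor mask, brain mask). A linked tumor
    annotation is used directly (on its native grid) when
    ``skip_segmentation`` is set or no predictor applies; otherwise the
    configured predictor is run patch-wise on the preprocessed scan.
    """
    if not ts.images:
        raise InvalidInputError(f"timestamp {ts.label} has no image")
    image = load_image(ts.images[0])
    provided_tumor = next((m for m in ts.masks if m[2] == "tumor"), None)
    provided_brain = next((m for m in ts.masks if m[2] == "brain"), None)
    brain = load_mask(provided_brain[0], kind="brain") if provided_brain else None
    inf = config.inference
    if brain is None and config.preprocessing.skull_strip:
        brain_pred = make_threshold_predictor(
            inf.brain_predictor_threshold, tuple(inf.brain_working_shape)
        )
        # brain extraction: single-shot on a downsampled copy of the scan
        norm = preprocess(
            image,
            PreprocessingConfig(
                target_spacing_mm=max(image.spacing),
                clip_upper_fraction=config.preprocessing.clip_upper_fraction,
                skull_strip=False,
            ),
        )
        brain = predict_downsampled(
            norm, brain_pred, inf.brain_working_shape, inf.binarization_threshold
        )
        if not np.allclose(norm.spacing, image.spacing):
            brain = None  # only usable when grids match; keep conservative
    pre = preprocess(image, config.preprocessing.to_config(), brain)
    if config.skip_segmentation and provided_tumor is not None:
        tumor = load_mask(provided_tumor[0], kind="tumor")
        return pre, tumor, brain
    predictor = make_threshold_predictor(inf.predictor_threshold, tuple(inf.patch_shape))
    grid = plan_patch_grid(pre.shape, inf.patch_shape, inf.min_overlap_fraction)
    prob = predict_patchwise(pre, predictor, grid, inf.fusion)
    tumor = binarize_probability(prob, inf.binarization_threshold, kind="tumor")
    return pre, tumor, brain


def _provenance(record: PatientRecord, ts_labels: Sequence[str], config: RunConfig) -> dict:
    inputs = []
    for ts in record.timestamps:
        if ts.label in ts_labels:
            inputs.extend(p.name for p in ts.images)
            inputs.extend(m[0].name for m in ts.masks)
    return {
        "patient_id": record.patient_id,
        "inputs": ",".join(sorted(inputs)),
        "config_hash": config.config_hash(),
        "software_version": __version__,
    }


def run_single_patient(
    record: PatientRecord,
    config: RunConfig,
    out_dir: str | Path,
    atlas: AtlasBundle | None = None,
) -> dict[str, StandardizedReport]:
    """Execute the configured task for one patient; writes masks + reports.

    Fully deterministic for fixed inputs and config: rerunning changes no
    file contents.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if atlas is None and config.atlas_path:
        atlas = load_atlas(config.atlas_path)
    reports: dict[str, StandardizedReport] = {}
    task = config.task
    if task in ("segment", "report_preop", "evaluate"):
        ts0 = record.timestamps[0]
        pre, tumor, _ = _segment_timestamp(ts0, config)
        save_mask(tumor, out_dir / f"{record.patient_id}_{ts0.label}_tumor_pred.nii.gz")
        if task == "report_preop":
            if atlas is None:
                raise ConfigError("preoperative reporting requires an atlas")
            transform = estimate_transform(pre, atlas.reference)
            tumor_ref = warp_mask(tumor, transform, atlas.reference)
            if tumor_ref.foreground_count() == 0 and tumor.foreground_count() > 0:
                raise InvalidInputError("tumor mask vanished during atlas warping")
            report = assemble_preop_report(
                tumor, tumor_ref, atlas, config.thresholds.to_report_config(),
                provenance=_provenance(record, [ts0.label], config),
            )
            serialize_report(report, out_dir, config.formats, f"{record.patient_id}_preop")
            reports["preoperative"] = report
    if task == "report_postop":
        if len(record.timestamps) < 2:
            raise InvalidInputError(
                "postoperative reporting needs two timestamps (preop + postop)"
            )
        ts0, ts1 = record.timestamps[0], record.timestamps[1]
        _, tumor_pre, _ = _segment_timestamp(ts0, config)
        _, tumor_post, _ = _segment_timestamp(ts1, config)
        report = assemble_postop_report(
            tumor_pre, tumor_post, config.thresholds.to_report_config(),
            provenance=_provenance(record, [ts0.label, ts1.label], config),
        )
        serialize_report(report, out_dir, config.formats, f"{record.patient_id}_postop")
        reports["postoperative"] = report
    return reports


def run_batch(
    cohort_dir: str | Path,
    config: RunConfig,
    out_dir: str | Path,
) -> tuple[dict, int]:
    """Sequential per-patient runs over a cohort folder.

    Per-patient failures are isolated and logged; the run continues.
    Returns (summary dict, exit code): 0 all succeeded, 2 partial failure.
    """
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patient_dirs = sorted(d for d in cohort_dir.iterdir() if d.is_dir())
    if not patient_dirs:
        raise InvalidInputError(f"no patient folders under {cohort_dir}")
    atlas = load_atlas(config.atlas_path) if config.atlas_path else None
    summary_rows = []
    content_rows = []
    eval_results = []
    failures = 0
    for pdir in patient_dirs:
        pid = pdir.name
        try:
            record = load_patient_record(pdir)
            for ts in record.timestamps:
                for p in ts.images:
                    content_rows.append({"patient_id": pid, "timestamp": ts.label,
                                         "file": p.name, "role": "image"})
                for m, parent, kind in ts.masks:
                    content_rows.append({"patient_id": pid, "timestamp": ts.label,
                                         "file": m.name, "role": f"{kind}_mask"})
            if config.task == "evaluate":
                ts0 = record.timestamps[0]
                gt_link = next((m for m in ts0.masks if m[2] == "tumor"), None)
                if gt_link is None:
                    raise InvalidInputError(f"{pid}: no ground-truth tumor mask")
                gt = load_mask(gt_link[0], kind="tumor")
                seg_config = config.model_copy(update={"skip_segmentation": False})
                _, pred, _ = _segment_timestamp(ts0, seg_config)
                if not pred.grid.same_geometry(gt.grid):
                    raise GeometryError(f"{pid}: prediction grid differs from ground truth")
                res = evaluate_patient(
                    pid, gt, pred,
                    DetectionRule(config.thresholds.detection_min_dice_pct),
                    config.thresholds.connectivity,
                )
                eval_results.append(res)
                summary_rows.append({"patient_id": pid, "status": "ok",
                                     "dice_pct": res.dice_pct, "detected": res.detected})
            else:
                reports = run_single_patient(record, config, out_dir / pid, atlas)
                row = {"patient_id": pid, "status": "ok"}
                for phase, rep in reports.items():
                    for k, v in rep.volumes.items():
                        row[f"{phase}_{k}"] = v
                    if rep.eor_pct is not None:
                        row["eor_pct"] = rep.eor_pct
                        row["resection_class"] = rep.resection_class
                summary_rows.append(row)
        except Exception as exc:
            logger.exception("patient %s failed", pid)
            failures += 1
            summary_rows.append({"patient_id": pid, "status": f"failed: {exc}"})
    pd.DataFrame(content_rows).to_csv(out_dir / "cohort_contents.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(out_dir / "cohort_summary.csv", index=False)
    summary: dict = {"n_patients": len(patient_dirs), "n_failures": failures}
    if eval_results:
        table = stratify_by_volume(
            CohortMetricsTable(rows=eval_results),
            config.thresholds.volume_cutoff_ml,
        )
        table.to_csv(out_dir / "cohort_metrics.csv")
        summary["metrics"] = table.pooled
    exit_code = 0 if failures == 0 else 2
    return summary, exit_code
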