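"""Three-tier segmentation evaluation: voxel-, patient-, and object-wise.

Voxel-wise: Dice overlap per patient. Patient-wise: was the tumor detected
at all (configurable rule, default any overlap), aggregated into
recall/precision/F1 over the cohort, with Dice-TP the mean Dice restricted
to detected patients. Object-wise: per connected component, a ground-truth
focus is recalled if a predicted component overlaps it, a predicted
component is a precision hit if it overlaps any ground-truth focus.
Cohort results can be stratified by ground-truth volume (small vs
non-small, cut-off 2 ml by default, 5 ml for diffuse lower-grade glioma
style cohorts) and pooled across cross-validation folds such that pooling
reproduces the statistics of the concatenated cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, InvalidInputError, InvalidParameterError
from .image_core import LabelMask, mask_volume_ml
from .reporting import CONNECTIVITY_STRUCTURES

__all__ = [
    "DetectionRule",
    "PatientEvalResult",
    "CohortMetricsTable",
    "dice_coefficient",
    "patient_detection",
    "evaluate_patient",
    "cohort_patient_metrics",
    "objectwise_metrics",
    "stratify_by_volume",
    "pool_fold_estimates",
]

DEFAULT_VOLUME_CUTOFF_ML = 2.0
LGG_VOLUME_CUTOFF_ML = 5.0


@dataclass(frozen=True)
class DetectionRule:
    """Patient-level true-positive rule: Dice strictly above ``min_dice_pct``.

    The default (0) counts any voxel overlap as a detection. For a
    tumor-free patient a non-empty prediction is a false positive and an
    empty prediction a true negative.
    """

    min_dice_pct: float = 0.0


@dataclass(frozen=True)
class PatientEvalResult:
    patient_id: str
    dice_pct: float
    gt_volume_ml: float
    detected: bool
    gt_empty: bool = False
    pred_empty: bool = False
    object_recall_pct: float | None = None
    object_precision_pct: float | None = None
    object_f1_pct: float | None = None
    n_gt_objects: int = 0
    n_pred_objects: int = 0
    fold_id: int = 0


def _check_pair(gt: LabelMask, pred: LabelMask) -> None:
    if gt.shape != pred.shape or not gt.grid.same_geometry(pred.grid):
        raise GeometryError("ground-truth and prediction masks must share a grid")


def dice_coefficient(gt: LabelMask, pred: LabelMask, both_empty_value: float = 100.0) -> float:
    """Dice overlap in percent: 100 x 2|A∩B| / (|A| + |B|).

    Both-empty masks score ``both_empty_value`` (default 100), the
    convention needed for tumor-free postoperative patients.
    """
    _check_pair(gt, pred)
    a = gt.labels > 0
    b = pred.labels > 0
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return both_empty_value
    inter = int(np.count_nonzero(a & b))
    return 100.0 * 2.0 * inter / (na + nb)


def patient_detection(gt: LabelMask, pred: LabelMask, rule: DetectionRule = DetectionRule()) -> bool:
    """Patient-level detection under the configured rule.

    For non-empty ground truth: detected iff Dice exceeds the rule's
    threshold. For empty ground truth the notion does not apply (the
    prediction is judged as FP/TN by the cohort aggregation); this function
    then returns whether the prediction is also empty.
    """
    _check_pair(gt, pred)
    if gt.foreground_count() == 0:
        return pred.foreground_count() == 0
    return dice_coefficient(gt, pred) > rule.min_dice_pct


def objectwise_metrics(
    gt: LabelMask,
    pred: LabelMask,
    connectivity: Literal[6, 18, 26] = 26,
    min_pair_dice_pct: float = 0.0,
) -> dict:
    """Per-patient object-wise recall / precision / F1 over connected foci.

    Default match rule: any voxel overlap between a ground-truth and a
    predicted component counts. ``min_pair_dice_pct`` optionally requires
    the per-pair Dice to exceed a threshold instead.
    """
    _check_pair(gt, pred)
    structure = CONNECTIVITY_STRUCTURES[connectivity]
    gt_lab, n_gt = ndimage.label(gt.labels > 0, structure=structure)
    pr_lab, n_pr = ndimage.label(pred.labels > 0, structure=structure)
    gt_sizes = np.bincount(gt_lab.reshape(-1), minlength=n_gt + 1)
    pr_sizes = np.bincount(pr_lab.reshape(-1), minlength=n_pr + 1)
    matched_gt = np.zeros(n_gt + 1, dtype=bool)
    matched_pr = np.zeros(n_pr + 1, dtype=bool)
    both = (gt_lab > 0) & (pr_lab > 0)
    if both.any():
        pair_idx, pair_counts = np.unique(
            gt_lab[both].astype(np.int64) * (n_pr + 1) + pr_lab[both], return_counts=True
        )
        for key, inter in zip(pair_idx, pair_counts):
            g, p = divmod(int(key), n_pr + 1)
            if min_pair_dice_pct <= 0.0:
                matched = inter >= 1
            else:
                matched = 100.0 * 2.0 * inter / (gt_sizes[g] + pr_sizes[p]) > min_pair_dice_pct
            if matched:
                matched_gt[g] = True
                matched_pr[p] = True
    recall = 100.0 * matched_gt[1:].sum() / n_gt if n_gt else None
    precision = 100.0 * matched_pr[1:].sum() / n_pr if n_pr else None
    f1 = None
    if recall is not None and precision is not None:
        f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    return {
        "object_recall_pct": recall,
        "object_precision_pct": precision,
        "object_f1_pct": f1,
        "n_gt_objects": int(n_gt),
        "n_pred_objects": int(n_pr),
    }


def evaluate_patient(
    patient_id: str,
    gt: LabelMask,
    pred: LabelMask,
    rule: DetectionRule = DetectionRule(),
    connectivity: Literal[6, 18, 26] = 26,
    fold_id: int = 0,
) -> PatientEvalResult:
    """All three metric tiers for one ground-truth/prediction pair."""
    obj = objectwise_metrics(gt, pred, connectivity)
    gt_empty = gt.foreground_count() == 0
    return PatientEvalResult(
        patient_id=patient_id,
        dice_pct=dice_coefficient(gt, pred),
        gt_volume_ml=mask_volume_ml(gt),
        detected=patient_detection(gt, pred, rule),
        gt_empty=gt_empty,
        pred_empty=pred.foreground_count() == 0,
        fold_id=fold_id,
        **obj,
    )


def cohort_patient_metrics(results: Sequence[PatientEvalResult]) -> dict:
    """Cohort-level patient-wise metrics.

    Recall over tumor patients, precision over positive predictions, F1
    harmonic mean; ``dice_mean`` averages all tumor patients, ``dice_tp``
    only detected ones. Undefined ratios (zero denominators) are reported
    as None and flagged, never as 0.
    """
    if not results:
        raise InvalidInputError("empty cohort")
    tumor = [r for r in results if not r.gt_empty]
    tumor_free = [r for r in results if r.gt_empty]
    tp = sum(1 for r in tumor if r.detected)
    fn = len(tumor) - tp
    fp = sum(1 for r in tumor_free if not r.pred_empty)
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else None
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else None
    f1 = None
    if recall is not None and precision is not None:
        f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    dices = [r.dice_pct for r in tumor]
    dices_tp = [r.dice_pct for r in tumor if r.detected]
    out = {
        "recall_pct": recall,
        "precision_pct": precision,
        "f1_pct": f1,
        "dice_mean": float(np.mean(dices)) if dices else None,
        "dice_sd": float(np.std(dices, ddof=1)) if len(dices) > 1 else None,
        "dice_tp_mean": float(np.mean(dices_tp)) if dices_tp else None,
        "dice_tp_sd": float(np.std(dices_tp, ddof=1)) if len(dices_tp) > 1 else None,
        "n_patients": len(results),
        "n_tumor_patients": len(tumor),
        "undefined_metrics": [
            k for k, v in {"recall_pct": recall, "precision_pct": precision}.items() if v is None
        ],
    }
    return out


@dataclass
class CohortMetricsTable:
    """Per-patient rows plus pooled per-stratum summaries."""

    rows: list[PatientEvalResult]
    cutoff_ml: float | None = None
    pooled: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.rows])
        if self.cutoff_ml is not None and not df.empty:
            df["stratum"] = np.where(df["gt_volume_ml"] < self.cutoff_ml, "small", "non-small")
        return df

    def to_csv(self, path) -> None:
        """One row per patient, then a pooled-summary block (mean ± sd style)."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            df.to_csv(fh, index=False)
            if self.pooled:
                fh.write("\n# pooled summaries\n")
                pd.DataFrame(self.pooled).T.to_csv(fh)


def stratify_by_volume(
    table: CohortMetricsTable, cutoff_ml: float = DEFAULT_VOLUME_CUTOFF_ML
) -> CohortMetricsTable:
    """Partition the cohort at a ground-truth volume cut-off and re-pool.

    Rows with ``gt_volume_ml`` strictly below the cut-off form the small
    stratum. Pooled patient-wise metrics are recomputed per stratum; an
    empty stratum is reported with count 0 and no metrics.
    """
    small = [r for r in table.rows if r.gt_volume_ml < cutoff_ml]
    large = [r for r in table.rows if r.gt_volume_ml >= cutoff_ml]
    pooled = {}
    for name, rows in (("small", small), ("non-small", large)):
        if rows:
            pooled[name] = {"count": len(rows), **cohort_patient_metrics(rows)}
        else:
            pooled[name] = {"count": 0, "empty_stratum": True}
    return CohortMetricsTable(rows=list(table.rows), cutoff_ml=cutoff_ml, pooled=pooled)


def pool_fold_estimates(per_fold: Sequence[Mapping[str, float]]) -> dict:
    """Pool per-fold {n, mean, sd} summaries into one cohort estimate.

    Pooled mean is the n-weighted mean. Pooled variance combines the
    within-fold sum of squares (n_i - 1) s_i^2 with the between-fold
    dispersion n_i (m_i - M)^2, divided by N - 1, so that pooling any
    partition of a cohort — including all-singleton folds — reproduces the
    mean and (ddof=1) standard deviation of the concatenated cohort
    exactly.
    """
    if not per_fold:
        raise InvalidInputError("no folds to pool")
    ns = np.array([f["n"] for f in per_fold], dtype=float)
    if np.any(ns < 1):
        raise InvalidInputError("fold sizes must be >= 1")
    means = np.array([f["mean"] for f in per_fold], dtype=float)
    sds = np.array([float(f.get("sd") or 0.0) for f in per_fold], dtype=float)
    if np.any((ns >= 2) & np.isnan(sds)):
        raise InvalidInputError("folds with n >= 2 must report an sd")
    n_total = ns.sum()
    pooled_mean = float((ns * means).sum() / n_total)
    if n_total < 2:
        return {"n": int(n_total), "mean": pooled_mean, "sd": None}
    ss_within = ((ns - 1) * sds**2).sum()
    ss_between = (ns * (means - pooled_mean) ** 2).sum()
    pooled_sd = float(math.sqrt((ss_within + ss_between) / (n_total - 1)))
    return {"n": int(n_total), "mean": pooled_mean, "sd": pooled_sd}
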