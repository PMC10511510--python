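"""Voxel-, patient- and object-wise metrics, stratification, fold pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorads.errors import GeometryError, InvalidInputError
from neurorads.evaluation import (
    CohortMetricsTable,
    DetectionRule,
    PatientEvalResult,
    cohort_patient_metrics,
    dice_coefficient,
    evaluate_patient,
    objectwise_metrics,
    patient_detection,
    pool_fold_estimates,
    stratify_by_volume,
)

from conftest import binary_mask


def random_mask_pair(rng, shape=(12, 12, 12), p=0.3):
    a = (rng.random(shape) < p).astype(int)
    b = (rng.random(shape) < p).astype(int)
    return binary_mask(a), binary_mask(b)


def dice_oracle(a, b):
    """Brute-force voxel counting, independent of the implementation."""
    na = int(np.count_nonzero(a.labels))
    nb = int(np.count_nonzero(b.labels))
    inter = int(np.count_nonzero((a.labels > 0) & (b.labels > 0)))
    if na + nb == 0:
        return 100.0
    return 200.0 * inter / (na + nb)


class TestDice:
    def test_identical_masks_full_score(self):
        m = binary_mask((np.random.default_rng(0).random((8, 8, 8)) > 0.5).astype(int))
        assert dice_coefficient(m, m) == 100.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((8, 8, 8), dtype=int); a[:2] = 1
        b = np.zeros((8, 8, 8), dtype=int); b[6:] = 1
        assert dice_coefficient(binary_mask(a), binary_mask(b)) == 0.0

    def test_forced_arithmetic_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=int); a[0, 0, 0] = a[0, 0, 1] = 1
        b = np.zeros((4, 4, 4), dtype=int); b[0, 0, 1] = b[0, 0, 2] = 1
        assert dice_coefficient(binary_mask(a), binary_mask(b)) == 50.0

    def test_both_empty_convention(self):
        e = binary_mask(np.zeros((4, 4, 4)))
        assert dice_coefficient(e, e) == 100.0
        assert dice_coefficient(e, e, both_empty_value=0.0) == 0.0

    def test_symmetric_and_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = random_mask_pair(rng)
            assert dice_coefficient(a, b) == dice_coefficient(b, a)
            assert dice_coefficient(a, b) == pytest.approx(dice_oracle(a, b))

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a, b = random_mask_pair(rng, shape=(6, 8, 10))
        ap = binary_mask(np.transpose(a.labels, (1, 2, 0)))
        bp = binary_mask(np.transpose(b.labels, (1, 2, 0)))
        assert dice_coefficient(a, b) == pytest.approx(dice_coefficient(ap, bp))

    def test_grid_mismatch_rejected(self):
        a = binary_mask(np.zeros((4, 4, 4)))
        b = binary_mask(np.zeros((4, 4, 4)), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(GeometryError):
            dice_coefficient(a, b)


class TestPatientDetection:
    def test_any_overlap_detects(self):
        a = np.zeros((8, 8, 8), dtype=int); a[2:6, 2:6, 2:6] = 1
        b = np.zeros((8, 8, 8), dtype=int); b[5, 5, 5] = 1
        assert patient_detection(binary_mask(a), binary_mask(b))

    def test_empty_prediction_is_a_miss(self):
        a = np.zeros((8, 8, 8), dtype=int); a[2:4] = 1
        assert not patient_detection(binary_mask(a), binary_mask(np.zeros((8, 8, 8))))

    def test_one_voxel_overlap_fails_strict_rule(self):
        a = np.zeros((10, 10, 10), dtype=int); a[0:5] = 1   # 500 voxels
        b = np.zeros((10, 10, 10), dtype=int); b[4:9] = 1   # 500, overlap 100
        ga, gb = binary_mask(a), binary_mask(b)
        # recomputed by counting: Dice = 200*100/1000 = 20%
        assert patient_detection(ga, gb, DetectionRule(0.0))
        assert not patient_detection(ga, gb, DetectionRule(25.0))


class TestCohortMetrics:
    @staticmethod
    def result(pid, dice, detected, gt_empty=False, pred_empty=False, vol=1.0, fold=0):
        return PatientEvalResult(pid, dice, vol, detected,
                                 gt_empty=gt_empty, pred_empty=pred_empty, fold_id=fold)

    def test_perfect_cohort(self):
        rows = [self.result(f"p{i}", 100.0, True) for i in range(4)]
        m = cohort_patient_metrics(rows)
        assert m["recall_pct"] == m["precision_pct"] == m["f1_pct"] == 100.0
        assert m["dice_mean"] == m["dice_tp_mean"] == 100.0

    def test_hand_computed_contingency(self):
        rows = [
            self.result("a", 80.0, True),
            self.result("b", 60.0, True),
            self.result("c", 0.0, False),  # missed tumor
        ]
        m = cohort_patient_metrics(rows)
        assert m["recall_pct"] == pytest.approx(66.6667, abs=1e-3)
        assert m["dice_mean"] == pytest.approx(46.6667, abs=1e-3)
        assert m["dice_tp_mean"] == pytest.approx(70.0)

    def test_false_positive_on_tumor_free_patient(self):
        rows = [
            self.result("a", 90.0, True),
            self.result("b", 85.0, True),
            self.result("c", 0.0, False, gt_empty=True, pred_empty=False),  # FP
        ]
        m = cohort_patient_metrics(rows)
        assert m["precision_pct"] == pytest.approx(66.6667, abs=1e-3)
        assert m["recall_pct"] == 100.0

    def test_undefined_metrics_reported_not_zero(self):
        rows = [self.result("a", 100.0, True, gt_empty=True, pred_empty=True)]
        m = cohort_patient_metrics(rows)
        assert m["recall_pct"] is None
        assert "recall_pct" in m["undefined_metrics"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidInputError):
            cohort_patient_metrics([])


class TestObjectwise:
    def two_focus_gt(self):
        gt = np.zeros((16, 16, 16), dtype=int)
        gt[2:5, 2:5, 2:5] = 1
        gt[10:13, 10:13, 10:13] = 1
        return gt

    def test_both_foci_covered(self):
        gt = self.two_focus_gt()
        m = objectwise_metrics(binary_mask(gt), binary_mask(gt))
        assert m["object_recall_pct"] == 100.0
        assert m["object_precision_pct"] == 100.0
        assert m["n_gt_objects"] == 2

    def test_only_larger_focus_found(self):
        gt = self.two_focus_gt()
        pred = np.zeros((16, 16, 16), dtype=int)
        pred[2:5, 2:5, 2:5] = 1
        m = objectwise_metrics(binary_mask(gt), binary_mask(pred))
        assert m["object_recall_pct"] == 50.0
        assert m["object_precision_pct"] == 100.0

    def test_spurious_blobs_hurt_precision(self):
        gt = np.zeros((16, 16, 16), dtype=int)
        gt[2:5, 2:5, 2:5] = 1
        pred = np.array(gt)
        pred[10:12, 2:4, 2:4] = 1
        pred[10:12, 10:12, 10:12] = 1
        m = objectwise_metrics(binary_mask(gt), binary_mask(pred))
        assert m["object_recall_pct"] == 100.0
        assert m["object_precision_pct"] == pytest.approx(33.3333, abs=1e-3)

    def test_matches_floodfill_oracle_on_random_pairs(self):
        from scipy import ndimage

        rng = np.random.default_rng(3)
        structure = ndimage.generate_binary_structure(3, 3)
        for _ in range(15):
            gt, pred = random_mask_pair(rng, shape=(10, 10, 10), p=0.15)
            m = objectwise_metrics(gt, pred)
            gl, ng = ndimage.label(gt.labels, structure=structure)
            pl, np_ = ndimage.label(pred.labels, structure=structure)
            hit_g = len({g for g in np.unique(gl[(gl > 0) & (pl > 0)])})
            hit_p = len({p for p in np.unique(pl[(gl > 0) & (pl > 0)])})
            if ng:
                assert m["object_recall_pct"] == pytest.approx(100.0 * hit_g / ng)
            if np_:
                assert m["object_precision_pct"] == pytest.approx(100.0 * hit_p / np_)

    def test_equals_patient_detection_for_unifocal_cohort(self):
        rng = np.random.default_rng(4)
        gt = np.zeros((12, 12, 12), dtype=int)
        gt[4:8, 4:8, 4:8] = 1
        for pred_hit in (True, False):
            pred = np.zeros((12, 12, 12), dtype=int)
            if pred_hit:
                pred[5:7, 5:7, 5:7] = 1
            else:
                pred[0:2, 0:2, 0:2] = 1
            m = objectwise_metrics(binary_mask(gt), binary_mask(pred))
            det = patient_detection(binary_mask(gt), binary_mask(pred))
            assert (m["object_recall_pct"] == 100.0) == det


class TestStratification:
    @staticmethod
    def rows(volumes):
        return [
            PatientEvalResult(f"p{i}", 80.0, v, True) for i, v in enumerate(volumes)
        ]

    @pytest.mark.parametrize("cutoff,volumes,expected_small", [
        (2.0, [0.5, 1.9, 2.0, 3.0], 2),
        (5.0, [0.5, 1.9, 2.0, 3.0], 4),
    ])
    def test_cutoffs(self, cutoff, volumes, expected_small):
        table = stratify_by_volume(CohortMetricsTable(self.rows(volumes)), cutoff)
        assert table.pooled["small"]["count"] == expected_small
        assert table.pooled["small"]["count"] + table.pooled["non-small"]["count"] == len(volumes)

    def test_empty_stratum_flagged(self):
        table = stratify_by_volume(CohortMetricsTable(self.rows([5.0, 6.0])), 2.0)
        assert table.pooled["small"] == {"count": 0, "empty_stratum": True}

    def test_counts_match_comparison_oracle(self):
        rng = np.random.default_rng(5)
        volumes = rng.uniform(0.1, 10.0, size=10)
        table = stratify_by_volume(CohortMetricsTable(self.rows(volumes)), 2.0)
        assert table.pooled["small"]["count"] == int((volumes < 2.0).sum())
        assert table.pooled["non-small"]["count"] == int((volumes >= 2.0).sum())

    def test_dataframe_carries_stratum_labels(self):
        table = stratify_by_volume(CohortMetricsTable(self.rows([1.0, 3.0])), 2.0)
        df = table.to_dataframe()
        assert list(df["stratum"]) == ["small", "non-small"]


class TestPooling:
    def test_identical_folds_pool_to_themselves(self):
        folds = [{"n": 4, "mean": 80.0, "sd": 5.0}] * 3
        pooled = pool_fold_estimates(folds)
        assert pooled["mean"] == pytest.approx(80.0)

    def test_two_folds_match_concatenation(self):
        # direct concatenation oracle over (80, 60) and (100, 80)
        values = np.array([80.0, 60.0, 100.0, 80.0])
        folds = [
            {"n": 2, "mean": 70.0, "sd": np.std([80.0, 60.0], ddof=1)},
            {"n": 2, "mean": 90.0, "sd": np.std([100.0, 80.0], ddof=1)},
        ]
        pooled = pool_fold_estimates(folds)
        assert pooled["mean"] == pytest.approx(values.mean())
        assert pooled["sd"] == pytest.approx(np.std(values, ddof=1))

    def test_singleton_folds_reproduce_cohort_stats(self):
        values = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        folds = [{"n": 1, "mean": v, "sd": None} for v in values]
        pooled = pool_fold_estimates(folds)
        assert pooled["mean"] == pytest.approx(values.mean())
        assert pooled["sd"] == pytest.approx(np.std(values, ddof=1))

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_concatenation_equivalence_for_random_partitions(self, data):
        values = np.array(data.draw(st.lists(
            st.floats(0.0, 100.0), min_size=3, max_size=25)))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        n_folds = data.draw(st.integers(1, len(values)))
        assignment = rng.integers(0, n_folds, size=len(values))
        folds = []
        for f in range(n_folds):
            sub = values[assignment == f]
            if len(sub) == 0:
                continue
            folds.append({
                "n": len(sub),
                "mean": sub.mean(),
                "sd": np.std(sub, ddof=1) if len(sub) > 1 else None,
            })
        pooled = pool_fold_estimates(folds)
        assert pooled["mean"] == pytest.approx(values.mean(), abs=1e-9)
        if len(values) > 1:
            assert pooled["sd"] == pytest.approx(np.std(values, ddof=1), abs=1e-7)

    def test_empty_fold_list_rejected(self):
        with pytest.raises(InvalidInputError):
            pool_fold_estimates([])


class TestEvaluatePatient:
    def test_all_tiers_populated(self):
        rng = np.random.default_rng(6)
        gt, pred = random_mask_pair(rng, shape=(10, 10, 10), p=0.2)
        res = evaluate_patient("p0", gt, pred)
        assert 0 <= res.dice_pct <= 100
        assert res.gt_volume_ml > 0
        assert res.n_gt_objects >= 1
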