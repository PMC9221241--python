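"""Metric oracles, algebraic identities, and stratification boundaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from feccnet.errors import InputError
from feccnet.metrics import (
    LESION_FREE,
    confusion_counts,
    dsc,
    evaluate,
    iou,
    miou,
    precision,
    recall,
    report_from_pairs,
    stratify_by_lesion_size,
)


def brute_force_counts(gt, pred):
    """Per-pixel loop oracle for the confusion tallies."""
    tp = fp = fn = tn = 0
    for g, p in zip(np.asarray(gt).ravel(), np.asarray(pred).ravel()):
        if g and p:
            tp += 1
        elif not g and p:
            fp += 1
        elif g and not p:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestConfusionCounts:
    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.uniform(size=(6, 6)) > 0.5).astype(np.uint8)
        c = confusion_counts(m, m)
        assert c.fp == c.fn == 0

    def test_enumerated_example(self):
        c = confusion_counts([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_counts_conserve_pixel_total(self, rng):
        gt = rng.uniform(size=(9, 7)) > 0.4
        pred = rng.uniform(size=(9, 7)) > 0.6
        assert confusion_counts(gt, pred).total == 63

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPixelMetrics:
    def test_perfect_prediction_scores_one(self, rng):
        m = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
        assert m.sum() > 0
        for f in (dsc, iou, recall, precision, miou):
            assert f(m, m) == 1.0

    def test_hand_counted_example(self):
        gt, pred = [1, 1, 0, 0], [1, 0, 1, 0]
        assert dsc(gt, pred) == pytest.approx(0.5)
        assert recall(gt, pred) == pytest.approx(0.5)
        assert precision(gt, pred) == pytest.approx(0.5)
        assert iou(gt, pred) == pytest.approx(1 / 3)
        assert miou(gt, pred) == pytest.approx(1 / 3)

    def test_disjoint_masks_score_zero_miou(self):
        assert miou([1, 0], [0, 1]) == 0.0

    def test_empty_empty_convention(self):
        z = np.zeros((4, 4))
        for f in (dsc, iou, recall, precision, miou):
            assert f(z, z) == 1.0

    def test_agreement_with_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(100):
            gt = rng.uniform(size=(16, 16)) > rng.uniform(0.2, 0.8)
            pred = rng.uniform(size=(16, 16)) > rng.uniform(0.2, 0.8)
            tp, fp, fn, tn = brute_force_counts(gt, pred)
            c = confusion_counts(gt, pred)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            if tp + fp + fn:
                assert dsc(gt, pred) == pytest.approx(2 * tp / (2 * tp + fp + fn))
                assert iou(gt, pred) == pytest.approx(tp / (tp + fp + fn))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        gt=hnp.arrays(np.int8, (5, 5), elements=st.integers(0, 1)),
        pred=hnp.arrays(np.int8, (5, 5), elements=st.integers(0, 1)),
    )
    def test_dsc_iou_identity_everywhere(self, gt, pred):
        d, j = dsc(gt, pred), iou(gt, pred)
        assert d == pytest.approx(2 * j / (1 + j), rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        gt=hnp.arrays(np.int8, (4, 6), elements=st.integers(0, 1)),
        pred=hnp.arrays(np.int8, (4, 6), elements=st.integers(0, 1)),
        seed=st.integers(0, 2**16),
    )
    def test_metrics_invariant_under_joint_spatial_permutation(self, gt, pred, seed):
        perm = np.random.default_rng(seed).permutation(24)
        gp, pp = gt.ravel()[perm], pred.ravel()[perm]
        for f in (dsc, miou, recall, precision):
            assert f(gt, pred) == pytest.approx(f(gp, pp))


class TestStratification:
    @pytest.mark.parametrize(
        "count,label",
        [(0, "lesion_free"), (1, "small"), (99, "small"), (100, "medium"),
         (999, "medium"), (1000, "large"), (500, "medium")],
    )
    def test_boundary_counts(self, count, label):
        mask = np.zeros(2048, dtype=np.uint8)
        mask[:count] = 1
        assert stratify_by_lesion_size(mask) == label

    def test_partition_property(self, rng):
        # every mask gets exactly one label from the documented set
        for _ in range(50):
            mask = rng.uniform(size=(40, 40)) > rng.uniform(0.1, 0.999)
            assert stratify_by_lesion_size(mask) in {
                LESION_FREE, "small", "medium", "large"
            }


class TestEvaluate:
    class _Stub:
        """Fixed-output predictor for report plumbing tests."""

        def __init__(self, outputs):
            self.outputs = outputs
            self.calls = 0

        def predict_mask(self, image):
            out = self.outputs[self.calls]
            self.calls += 1
            return out

    def test_perfect_predictor_scores_one_everywhere(self, rng):
        from feccnet.data_io import SliceRecord

        masks = []
        for count in (50, 500, 1200):
            m = np.zeros((64, 64), dtype=np.uint8)
            m.ravel()[:count] = 1
            masks.append(m)
        records = [
            SliceRecord(image=np.zeros((64, 64)), mask=m, case_id="c", slice_index=i,
                        stratum=stratify_by_lesion_size(m))
            for i, m in enumerate(masks)
        ]
        report = evaluate(self._Stub(masks), records)
        for stratum in ("small", "medium", "large", "overall"):
            for key in ("dsc", "miou", "recall", "precision"):
                assert report[stratum][key] == 1.0

    def test_all_background_predictor_has_zero_recall(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[:2] = 1
        report = report_from_pairs([(gt, np.zeros_like(gt))])
        assert report["small"]["recall"] == 0.0

    def test_report_rows_match_hand_computed_means(self):
        # three slices: two small (dsc 1 and 0.5), one lesion-free (excluded)
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, :2] = 1
        b = np.zeros((4, 4), dtype=np.uint8)
        b[0, 0] = 1
        b_pred = np.zeros_like(b)
        b_pred[0, :3] = 1  # tp=1, fp=2 -> dsc = 2/(2+2) = 0.5
        free = np.zeros((4, 4), dtype=np.uint8)
        report = report_from_pairs([(a, a), (b, b_pred), (free, free)])
        assert report.n_lesion_free == 1
        assert report["small"]["n_slices"] == 2
        assert report["small"]["dsc"] == pytest.approx((1.0 + 0.5) / 2)
        assert report["overall"]["precision"] == pytest.approx((1.0 + 1 / 3) / 2)

    def test_empty_stratum_absent_not_zero(self):
        gt = np.zeros((40, 40), dtype=np.uint8)
        gt[:10] = 1  # 400 px -> medium only
        report = report_from_pairs([(gt, gt)])
        assert "small" not in report.rows
        assert "large" not in report.rows

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        gt = np.zeros((40, 40), dtype=np.uint8)
        gt[:10] = 1
        report = report_from_pairs([(gt, gt)])
        report.to_csv(tmp_path / "report.csv")
        frame = pd.read_csv(tmp_path / "report.csv")
        assert list(frame.columns) == ["stratum", "n_slices", "dsc", "miou",
                                       "recall", "precision"]
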