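"""IoU, recall at the validity cutoff, peak-frame comparison, mask BCE."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import iou_pixel_count_oracle, make_gt_set
from larkin.annotations_io import (
    AnnotationSet,
    FrameAnnotation,
    StructureLabel,
    StructureMask,
    VideoMeta,
)
from larkin.errors import DataError
from larkin.evaluation import (
    FrameIoU,
    compare_peak_iou,
    evaluate,
    iou,
    mask_bce_loss,
    match_detections,
)


class TestIoU:
    def test_identical_masks(self, square_mask):
        assert iou(square_mask, square_mask) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:2, :2] = True
        b[5:, 5:] = True
        assert iou(a, b) == 0.0

    def test_offset_rectangles_hand_count(self):
        # two 2x3 rectangles offset by one column: 6 px each, 4 px overlap
        a = np.zeros((6, 6), bool)
        b = np.zeros((6, 6), bool)
        a[1:3, 1:4] = True
        b[1:3, 2:5] = True
        assert iou(a, b) == pytest.approx(4 / 8)

    def test_symmetry_and_errors(self, square_mask):
        other = np.roll(square_mask, 7, axis=1)
        assert iou(square_mask, other) == iou(other, square_mask)
        with pytest.raises(DataError):
            iou(square_mask, np.zeros((3, 3), bool))
        with pytest.raises(DataError):
            iou(np.zeros((8, 8), bool), np.zeros((8, 8), bool))

    @given(seed=st.integers(0, 200))
    @settings(max_examples=40)
    def test_matches_pixel_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(4, 64)), int(rng.integers(4, 64)))
        a = rng.random(shape) < 0.3
        b = rng.random(shape) < 0.3
        if not (a | b).any():
            a[0, 0] = True
        assert iou(a, b) == iou_pixel_count_oracle(a, b)


def _mask(label, area_rows, score=None):
    raster = np.zeros((32, 32), bool)
    raster[area_rows] = True
    return StructureMask(label, raster=raster, score=score)


class TestMatchDetections:
    meta = VideoMeta(32, 32, 30, 1)

    def test_highest_score_wins(self):
        lo = _mask(StructureLabel.TVC, (slice(0, 4), slice(0, 4)), score=0.7)
        hi = _mask(StructureLabel.TVC, (slice(10, 14), slice(0, 4)), score=0.9)
        frame = FrameAnnotation(0, [lo, hi])
        assert match_detections(frame, StructureLabel.TVC, self.meta) is hi

    def test_no_instance_returns_none(self):
        frame = FrameAnnotation(0, [])
        assert match_detections(frame, StructureLabel.TVC, self.meta) is None

    def test_score_tie_broken_by_area_then_order(self):
        big = _mask(StructureLabel.TVC, (slice(0, 10), slice(0, 12)), score=0.5)   # 120 px
        small = _mask(StructureLabel.TVC, (slice(20, 28), slice(0, 10)), score=0.5)  # 80 px
        assert match_detections(FrameAnnotation(0, [small, big]), StructureLabel.TVC, self.meta) is big
        twin = _mask(StructureLabel.TVC, (slice(12, 20), slice(20, 30)), score=0.5)  # 80 px
        assert match_detections(FrameAnnotation(0, [small, twin]), StructureLabel.TVC, self.meta) is small


def _contingency_sets(n_frames, tvc_good, c1_good, meta=None):
    """gt + predictions realizing a chosen TP/FN contingency table.

    Good frames get an identical mask (IoU 1); bad frames get a disjoint
    mask (IoU 0, below any positive cutoff).
    """
    meta = meta or VideoMeta(48, 48, 30, n_frames)
    gt_frames, pred_frames = [], []
    base = np.zeros(meta.shape, bool)
    base[10:20, 10:20] = True
    off = np.zeros(meta.shape, bool)
    off[30:40, 30:40] = True
    c1 = np.zeros(meta.shape, bool)
    c1[2:8, 2:8] = True
    c1_off = np.zeros(meta.shape, bool)
    c1_off[40:46, 2:8] = True
    for t in range(n_frames):
        gt_frames.append(FrameAnnotation(t, [
            StructureMask(StructureLabel.TVC, raster=base.copy()),
            StructureMask(StructureLabel.C1_SPINOUS, raster=c1.copy()),
        ]))
        pred_frames.append(FrameAnnotation(t, [
            StructureMask(StructureLabel.TVC, raster=(base if t < tvc_good else off).copy(), score=0.9),
            StructureMask(StructureLabel.C1_SPINOUS, raster=(c1 if t < c1_good else c1_off).copy(), score=0.9),
        ]))
    gt = AnnotationSet(meta=meta, frames=gt_frames, kind="ground_truth")
    pred = AnnotationSet(meta=meta, frames=pred_frames, kind="prediction")
    return gt, pred


class TestEvaluate:
    def test_reported_test_set_contingency(self):
        """532 annotated frames; 462 valid TVC detections and 531 valid C1
        detections must give recall 86.8% and 99.8%."""
        gt, pred = _contingency_sets(532, tvc_good=462, c1_good=531)
        report = evaluate(gt, pred, threshold=0.3)
        tvc = report.per_label[StructureLabel.TVC]
        c1 = report.per_label[StructureLabel.C1_SPINOUS]
        assert (tvc.n_tp, tvc.n_fn) == (462, 70)
        assert (c1.n_tp, c1.n_fn) == (531, 1)
        assert round(tvc.recall_percent, 1) == 86.8
        assert round(c1.recall_percent, 1) == 99.8

    def test_perfect_predictions(self, small_meta):
        blob = np.zeros(small_meta.shape, bool)
        blob[5:12, 5:12] = True
        gt = make_gt_set(small_meta, {t: {StructureLabel.TVC: blob} for t in range(4)})
        pred = AnnotationSet(meta=small_meta, frames=gt.frames, kind="prediction")
        report = evaluate(gt, pred)
        s = report.per_label[StructureLabel.TVC]
        assert s.recall_percent == 100.0
        assert s.iou_mean == 1.0 and s.iou_min == 1.0

    def test_missing_prediction_is_fn_with_missing_iou(self, small_meta):
        blob = np.zeros(small_meta.shape, bool)
        blob[5:12, 5:12] = True
        gt = make_gt_set(small_meta, {0: {StructureLabel.TVC: blob}})
        pred = AnnotationSet(meta=small_meta, frames=[FrameAnnotation(0, [])], kind="prediction")
        report = evaluate(gt, pred)
        rec = report.per_frame[0]
        assert rec.iou is None and not rec.is_tp
        s = report.per_label[StructureLabel.TVC]
        assert s.n_fn == 1 and s.iou_mean == 0.0 and s.iou_mean_detected is None

    def test_false_positive_counted_but_outside_recall(self, small_meta):
        blob = np.zeros(small_meta.shape, bool)
        blob[5:12, 5:12] = True
        gt = make_gt_set(small_meta, {0: {StructureLabel.TVC: blob}})
        pred = AnnotationSet(meta=small_meta, frames=[FrameAnnotation(0, [
            StructureMask(StructureLabel.TVC, raster=blob),
            StructureMask(StructureLabel.C1_SPINOUS, raster=blob),
        ])], kind="prediction")
        report = evaluate(gt, pred)
        assert report.n_false_positive[StructureLabel.C1_SPINOUS] == 1
        assert StructureLabel.C1_SPINOUS not in report.per_label

    def test_recall_monotone_in_threshold(self):
        gt, pred = _contingency_sets(20, tvc_good=12, c1_good=20)
        recalls = [
            evaluate(gt, pred, threshold=t).per_label[StructureLabel.TVC].recall_percent
            for t in (0.1, 0.3, 0.5, 0.9)
        ]
        assert recalls == sorted(recalls, reverse=True)

    def test_single_frame_drop_below_threshold_loses_one_tp(self, small_meta):
        blob = np.zeros(small_meta.shape, bool)
        blob[5:15, 5:15] = True
        gt = make_gt_set(small_meta, {t: {StructureLabel.TVC: blob} for t in range(3)})
        pred_frames = [FrameAnnotation(t, [StructureMask(StructureLabel.TVC, raster=blob.copy())])
                       for t in range(3)]
        # shift frame 1's prediction far enough that IoU < 0.3
        bad = np.zeros(small_meta.shape, bool)
        bad[20:30, 20:30] = True
        before = evaluate(gt, AnnotationSet(meta=small_meta, frames=pred_frames, kind="prediction"))
        pred_frames[1] = FrameAnnotation(1, [StructureMask(StructureLabel.TVC, raster=bad)])
        after = evaluate(gt, AnnotationSet(meta=small_meta, frames=pred_frames, kind="prediction"))
        assert before.per_label[StructureLabel.TVC].n_tp - after.per_label[StructureLabel.TVC].n_tp == 1

    def test_meta_mismatch_rejected(self, small_meta):
        blob = np.zeros(small_meta.shape, bool)
        blob[5:12, 5:12] = True
        gt = make_gt_set(small_meta, {0: {StructureLabel.TVC: blob}})
        other = AnnotationSet(meta=VideoMeta(16, 16, 30, 1), frames=[], kind="prediction")
        with pytest.raises(DataError):
            evaluate(gt, other)


def _series(values, peak_frames=()):
    return [
        FrameIoU(i, StructureLabel.TVC, iou=v, is_tp=v is not None and v >= 0.3)
        for i, v in enumerate(values)
    ]


class TestComparePeakIoU:
    def test_identical_groups_mean_equal_p_near_one(self):
        vals = [0.3, 0.5, 0.4, 0.3, 0.5, 0.4]
        cmp = compare_peak_iou(_series(vals), peak_frames={0, 1, 2})
        assert cmp.peak_mean == pytest.approx(cmp.lower_mean)
        assert cmp.p_value == pytest.approx(1.0)

    def test_separated_groups_against_hand_welch(self):
        peak_vals = [0.10, 0.12, 0.11]
        lower_vals = [0.90, 0.88, 0.92]
        cmp = compare_peak_iou(_series(peak_vals + lower_vals), peak_frames={0, 1, 2})
        assert cmp.peak_mean == pytest.approx(np.mean(peak_vals))
        assert cmp.lower_mean == pytest.approx(np.mean(lower_vals))
        # hand-computed Welch statistic -> p through the t distribution
        m1, m2 = np.mean(peak_vals), np.mean(lower_vals)
        v1, v2 = np.var(peak_vals, ddof=1), np.var(lower_vals, ddof=1)
        n1 = n2 = 3
        t_stat = (m1 - m2) / math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p_hand = 2 * stats.t.sf(abs(t_stat), df)
        assert cmp.p_value == pytest.approx(p_hand, rel=1e-9)

    def test_cross_check_against_statsmodels(self):
        rng = np.random.default_rng(11)
        peak = np.clip(rng.normal(0.38, 0.19, 25), 0, 1)
        lower = np.clip(rng.normal(0.44, 0.19, 80), 0, 1)
        series = _series(list(peak) + list(lower))
        cmp = compare_peak_iou(series, peak_frames=set(range(25)))
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        _, p_sm, _ = sm_ttest(peak, lower, usevar="unequal")
        assert cmp.p_value == pytest.approx(p_sm, rel=1e-8)

    def test_constant_groups_report_means_and_degenerate_p(self):
        """Welch's t is undefined for truly constant groups; with float data
        the variance is only numerically zero, so the p-value is either
        absent or vanishingly small — the means carry the signal."""
        cmp = compare_peak_iou(_series([0.1, 0.1, 0.1, 0.9, 0.9, 0.9]), peak_frames={0, 1, 2})
        assert cmp.peak_mean == pytest.approx(0.1)
        assert cmp.lower_mean == pytest.approx(0.9)
        assert cmp.p_value is None or cmp.p_value < 1e-10

    def test_tiny_group_omits_p(self):
        cmp = compare_peak_iou(_series([0.2, 0.5, 0.6, 0.7]), peak_frames={0})
        assert cmp.p_value is None and cmp.peak_n == 1

    def test_missing_iou_frames_excluded(self):
        series = _series([0.2, None, 0.5, 0.6, None, 0.7])
        cmp = compare_peak_iou(series, peak_frames={0, 1})
        assert cmp.peak_n == 1 and cmp.lower_n == 3

    def test_null_p_values_uniform(self):
        """Under the null (both groups from the same normal), Welch p-values
        must be uniform on [0, 1]; 1000 simulations, KS test at alpha=0.01."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(1000):
            vals = np.clip(rng.normal(0.5, 0.08, 20), 0, 1)
            series = _series(list(vals))
            cmp = compare_peak_iou(series, peak_frames=set(range(10)))
            pvals.append(cmp.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_mannwhitney_selectable(self):
        series = _series([0.1, 0.2, 0.15, 0.8, 0.9, 0.85])
        cmp = compare_peak_iou(series, peak_frames={0, 1, 2}, test="mannwhitney")
        expected = stats.mannwhitneyu([0.1, 0.2, 0.15], [0.8, 0.9, 0.85], alternative="two-sided")
        assert cmp.test_name == "mannwhitney"
        assert cmp.p_value == pytest.approx(float(expected.pvalue))


class TestMaskBceLoss:
    def test_uniform_half_probability_is_ln2(self):
        y = (np.arange(28 * 28).reshape(28, 28) % 3 == 0).astype(float)
        assert mask_bce_loss(y, np.full((28, 28), 0.5)) == pytest.approx(math.log(2), abs=1e-12)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25)
    def test_perfect_prediction_is_clamp_limited(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random((28, 28)) < 0.4).astype(float)
        assert mask_bce_loss(y, y) <= 1.01e-7

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(5)
        y = (rng.random((4, 4)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (4, 4))
        total = 0.0
        for i in range(4):
            for j in range(4):
                total += y[i, j] * math.log(p[i, j]) + (1 - y[i, j]) * math.log(1 - p[i, j])
        assert mask_bce_loss(y, p) == pytest.approx(-total / 16, rel=1e-12)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25)
    def test_minimized_at_truth(self, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random((8, 8)) < 0.5).astype(float)
        at_truth = mask_bce_loss(y, y)
        perturbed = np.clip(y + rng.uniform(-0.3, 0.3, y.shape), 0, 1)
        assert at_truth <= mask_bce_loss(y, perturbed) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            mask_bce_loss(np.zeros((4, 4)), np.full((5, 5), 0.5))
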