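import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import linear_sum_assignment

from mcseg.metrics import (
    DetectionObject,
    FROCCurve,
    bootstrap_pauc,
    froc_curve,
    iou,
    iou_per_object,
    match_detections,
    mean_iou_per_image,
    objects_from_mask,
    operating_point,
    partial_auc,
)


def _obj(centroid, pixels=()):
    rows = np.array([p[0] for p in pixels], dtype=int)
    cols = np.array([p[1] for p in pixels], dtype=int)
    return DetectionObject(centroid=centroid, rows=rows, cols=cols)


def _disc(center, radius):
    pts = [
        (r, c)
        for r in range(center[0] - radius, center[0] + radius + 1)
        for c in range(center[1] - radius, center[1] + radius + 1)
        if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2
    ]
    return _obj((float(center[0]), float(center[1])), pts)


class TestIoU:
    def test_identical_and_disjoint_masks(self):
        a = np.zeros((8, 8), dtype=bool)
        a[:3] = True
        assert iou(a, a) == 1.0
        assert iou(a, ~a) == 0.0

    def test_partial_overlap_small_case(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0:2] = True  # 2x1 rectangle
        b[0, 1:3] = True  # 2x1 rectangle sharing one pixel
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_empty_vs_empty_defined_as_one(self):
        z = np.zeros((4, 4), dtype=bool)
        assert iou(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    @settings(derandomize=True, max_examples=50)
    @given(
        a=arrays(bool, (8, 8), elements=st.booleans()),
        b=arrays(bool, (8, 8), elements=st.booleans()),
    )
    def test_symmetric_bounded_and_maximal_on_equality(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)
        assert iou(a, a) == 1.0
        if v == 1.0:
            assert np.array_equal(a, b)


class TestMeanIoUPerImage:
    def test_perfect_prediction_scores_one(self):
        truth = np.random.default_rng(0).random((16, 16)) < 0.1
        assert mean_iou_per_image(truth, truth) == 1.0

    def test_all_background_prediction_closed_form(self):
        truth = np.zeros((100, 100), dtype=bool)
        truth[:10, :10] = True  # foreground fraction f = 0.01
        pred = np.zeros_like(truth)
        assert mean_iou_per_image(pred, truth) == pytest.approx(0.5 * 0.99)

    def test_inverted_half_foreground_scores_zero(self):
        truth = np.zeros((10, 10), dtype=bool)
        truth[:5] = True
        assert mean_iou_per_image(~truth, truth) == 0.0


class TestIoUPerObject:
    def test_exact_objects_score_one(self):
        objs = [_disc((5, 5), 2), _disc((20, 20), 3)]
        assert iou_per_object(objs, objs) == 1.0

    def test_no_intersection_scores_zero(self):
        pred = [_disc((5, 5), 2)]
        truth = [_disc((20, 20), 2)]
        assert iou_per_object(pred, truth) == 0.0

    def test_half_matched_pair_averages(self):
        t1 = _obj((0.0, 1.5), [(0, 0), (0, 1), (0, 2), (0, 3)])
        p1 = _obj((0.0, 2.5), [(0, 2), (0, 3), (0, 4), (0, 5)])  # IoU 2/6 = 1/3... pick exact
        # construct IoU exactly 0.5: truth 2 px, pred 2px sharing... use 1 overlapping of 3 union
        t_a = _obj((0.0, 0.5), [(0, 0), (0, 1)])
        p_a = _obj((0.0, 1.0), [(0, 1)])  # IoU 1/2
        t_b = _obj((5.0, 5.0), [(5, 5)])
        result = iou_per_object([p_a], [t_a, t_b])
        assert result == pytest.approx((0.5 + 0.0) / 2)

    def test_empty_truth_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            out = iou_per_object([_disc((5, 5), 2)], [])
        assert math.isnan(out)


class TestMatchDetections:
    def test_coincident_point_is_true_positive(self):
        res = match_detections([_disc((10, 10), 2)], [_obj((10.0, 10.0))])
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_six_pixels_away_fails_both_rules(self):
        res = match_detections([_obj((10.0, 16.0), [(10, 16)])], [_obj((10.0, 10.0), [(10, 10)])])
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_five_pixel_distance_is_inclusive(self):
        res = match_detections([_obj((10.0, 15.0), [(10, 15)])], [_obj((10.0, 10.0), [(10, 10)])])
        assert res.tp == 1

    def test_iou_rule_matches_distant_centroids(self):
        # a long object whose centroid sits > 5 px from the truth centroid but
        # overlapping with IoU >= 0.3
        pix = [(0, c) for c in range(20)]
        pred = _obj((0.0, 9.5), pix)
        truth = _obj((0.0, 2.0), [(0, c) for c in range(8)])  # IoU 8/20 = 0.4
        res = match_detections([pred], [truth], max_distance_px=5.0)
        assert res.tp == 1

    def test_one_to_one_matching(self):
        truth = [_obj((10.0, 10.0))]
        preds = [_obj((10.0, 11.0)), _obj((10.0, 12.0))]
        res = match_detections(preds, truth)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)
        assert res.pairs == [(0, 0)]

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_matches_optimal_assignment_cardinality(self, seed):
        # audit: on small scenes greedy one-to-one matching should almost
        # always reach the maximum-cardinality assignment
        rng = np.random.default_rng(seed)
        preds = [_obj(tuple(rng.uniform(0, 30, 2))) for _ in range(rng.integers(1, 7))]
        truths = [_obj(tuple(rng.uniform(0, 30, 2))) for _ in range(rng.integers(1, 7))]
        res = match_detections(preds, truths)
        # Hungarian on the candidate graph (1 where matchable)
        cost = np.ones((len(preds), len(truths)))
        for i, p in enumerate(preds):
            for j, t in enumerate(truths):
                d = math.hypot(p.centroid[0] - t.centroid[0], p.centroid[1] - t.centroid[1])
                if d <= 5.0:
                    cost[i, j] = 0.0
        ri, ci = linear_sum_assignment(cost)
        optimal_tp = int((cost[ri, ci] == 0).sum())
        assert res.tp == optimal_tp


class TestObjectsFromMask:
    def test_components_and_centroids(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[7, 7] = True
        objs = objects_from_mask(mask)
        assert len(objs) == 2
        assert sorted(o.area for o in objs) == [1, 4]


class TestPartialAUC:
    def _curve(self, fp, tpr):
        return FROCCurve(thresholds=np.linspace(1, 0, len(fp)), tpr=np.array(tpr),
                         fp_per_cm2=np.array(fp))

    def test_flat_one_scores_one(self):
        assert partial_auc(self._curve([0.0, 2.0], [1.0, 1.0])) == pytest.approx(1.0)

    def test_flat_zero_scores_zero(self):
        assert partial_auc(self._curve([0.0, 2.0], [0.0, 0.0])) == pytest.approx(0.0)

    def test_linear_ramp_scores_half(self):
        fp = np.linspace(0, 1, 11)
        assert partial_auc(self._curve(fp, fp)) == pytest.approx(0.5)

    def test_invariant_under_interpolated_points(self):
        fp = np.array([0.0, 0.4, 1.0])
        tpr = np.array([0.2, 0.6, 0.9])
        base = partial_auc(self._curve(fp, tpr))
        # insert linearly interpolated midpoints: integral must not change
        fp2 = np.array([0.0, 0.2, 0.4, 0.7, 1.0])
        tpr2 = np.array([0.2, 0.4, 0.6, 0.75, 0.9])
        assert partial_auc(self._curve(fp2, tpr2)) == pytest.approx(base)

    def test_constant_extrapolation_beyond_curve_end(self):
        # curve ends at fp = 0.5: TPR held constant out to 1.0
        val = partial_auc(self._curve([0.0, 0.5], [1.0, 1.0]))
        assert val == pytest.approx(1.0)


class TestOperatingPoint:
    def test_ideal_point_wins(self):
        c = FROCCurve(thresholds=[0.9, 0.5], tpr=[1.0, 0.8], fp_per_cm2=[0.0, 1.0])
        assert operating_point(c) == 0.9

    def test_distance_comparison(self):
        c = FROCCurve(thresholds=[0.7, 0.2], tpr=[0.9, 0.95], fp_per_cm2=[0.4, 1.0])
        # distances: sqrt(.4^2+.1^2)=0.412 vs sqrt(1+.0025)=1.001
        assert operating_point(c) == 0.7

    def test_single_point_curve(self):
        c = FROCCurve(thresholds=[0.5], tpr=[0.6], fp_per_cm2=[0.3])
        assert operating_point(c) == 0.5

    def test_ties_break_to_larger_threshold(self):
        c = FROCCurve(thresholds=[0.3, 0.8], tpr=[0.9, 0.9], fp_per_cm2=[0.2, 0.2])
        assert operating_point(c) == 0.8


@pytest.fixture(scope="module")
def froc_images(phantom_bench):
    from mcseg.metrics import FROCImage, truth_objects_from_annotations
    from mcseg.proximity import proximity_map

    images = []
    for item in phantom_bench[:8]:
        proximity = proximity_map(item["truth"], xi=10, alpha=1)
        truths = truth_objects_from_annotations(item["annotations"], item["truth"])
        images.append(
            FROCImage(
                proximity=proximity,
                blob_objects=item["objects"],
                truth_objects=truths,
                area_cm2=item["image"].area_cm2,
            )
        )
    return images


class TestFROCOnPhantoms:
    def test_low_threshold_reaches_high_tpr(self, froc_images):
        curve = froc_curve(froc_images, p_thr_grid=np.array([0.0]), o_thr=0.3)
        assert curve.tpr[0] >= 0.9

    def test_unit_threshold_suppresses_false_positives(self, froc_images):
        curve = froc_curve(froc_images, p_thr_grid=np.array([1.0]), o_thr=0.3)
        assert curve.fp_per_cm2[0] <= 0.5

    def test_tpr_monotone_in_threshold(self, froc_images):
        grid = np.linspace(0, 1, 11)
        curve = froc_curve(froc_images, p_thr_grid=grid, o_thr=0.3)
        assert np.all(np.diff(curve.tpr) <= 1e-12)

    def test_bootstrap_is_seeded_and_brackets_the_point_estimate(self, froc_images):
        a = bootstrap_pauc(froc_images, n_bootstrap=25, seed=11)
        b = bootstrap_pauc(froc_images, n_bootstrap=25, seed=11)
        assert a == b
        assert a[1] <= a[0] <= a[2]

    def test_bootstrap_of_identical_images_has_zero_width(self, froc_images):
        same = [froc_images[0], froc_images[0], froc_images[0]]
        mean, lo, hi = bootstrap_pauc(same, n_bootstrap=10, seed=0)
        assert lo == pytest.approx(hi)

    def test_pooled_tpr_consistency(self, froc_images):
        from mcseg.fusion import combine
        from mcseg.metrics import match_detections
        from mcseg.proximity import threshold_map

        thr = 0.5
        tp = n_truth = 0
        for im in froc_images:
            region = threshold_map(im.proximity, thr)
            fused = combine(im.blob_objects, region, o_thr=0.3)
            preds = [DetectionObject(centroid=o.centroid, rows=o.rows, cols=o.cols)
                     for o in fused.objects]
            res = match_detections(preds, im.truth_objects)
            tp += res.tp
            n_truth += len(im.truth_objects)
        curve = froc_curve(froc_images, p_thr_grid=np.array([thr]), o_thr=0.3)
        assert curve.tpr[0] == pytest.approx(tp / n_truth)
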