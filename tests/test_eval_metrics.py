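import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsidefect.hypercube import BoundingBox
from hsidefect.eval_metrics import (
    MatchCounts,
    accuracy,
    confusion_matrix,
    evaluate_detections,
    f1_from_precision_recall,
    iou,
    match_detections,
    mean_ap,
    mean_iou,
    pr_curve_and_ap,
    precision_recall_f1,
    round_half_up,
)


def pixel_set(b: BoundingBox) -> set:
    return {(x, y) for x in range(b.x0, b.x1) for y in range(b.y0, b.y1)}


def brute_force_iou(a: BoundingBox, b: BoundingBox) -> float:
    sa, sb = pixel_set(a), pixel_set(b)
    return len(sa & sb) / len(sa | sb)


class TestIoU:
    def test_identical(self):
        b = BoundingBox(2, 3, 9, 11)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 15, 15)) == 0.0

    def test_half_overlap_case(self):
        a, b = BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10)
        assert iou(a, b) == pytest.approx(50 / 150)
        assert iou(a, b) == pytest.approx(brute_force_iou(a, b))

    def test_random_boxes_match_pixel_counting(self, rng):
        for _ in range(100):
            x0, y0 = rng.integers(0, 10, 2)
            a = BoundingBox(x0, y0, x0 + rng.integers(1, 8), y0 + rng.integers(1, 8))
            x0, y0 = rng.integers(0, 10, 2)
            b = BoundingBox(x0, y0, x0 + rng.integers(1, 8), y0 + rng.integers(1, 8))
            assert iou(a, b) == pytest.approx(brute_force_iou(a, b))


boxes = st.tuples(
    st.integers(0, 20), st.integers(0, 20), st.integers(1, 10), st.integers(1, 10)
).map(lambda t: BoundingBox(t[0], t[1], t[0] + t[2], t[1] + t[3]))


class TestIoUProperties:
    @settings(max_examples=100, deadline=None)
    @given(a=boxes, b=boxes)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)

    @settings(max_examples=50, deadline=None)
    @given(a=boxes)
    def test_self_iou_is_one(self, a):
        assert iou(a, a) == 1.0


class TestF1Properties:
    @settings(max_examples=100, deadline=None)
    @given(
        p=st.floats(0.0, 1.0, allow_nan=False),
        r=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_bounded_by_min_and_mean(self, p, r):
        f1 = f1_from_precision_recall(p, r)
        assert 0.0 <= f1 <= min(max(p, r), (p + r) / 2) + 1e-12


class TestPrecisionRecallF1:
    def test_table1_cbb_row(self):
        assert round_half_up(f1_from_precision_recall(0.977, 0.984)) == 0.980

    def test_table2_yolo_cbb_row(self):
        assert round_half_up(f1_from_precision_recall(0.600, 0.643)) == 0.621

    def test_perfect(self):
        assert f1_from_precision_recall(1.0, 1.0) == 1.0

    def test_zero_case(self):
        assert f1_from_precision_recall(0.0, 0.0) == 0.0

    def test_counts_to_prf(self):
        p, r, f1 = precision_recall_f1(MatchCounts(tp=8, fp=2, fn=4))
        assert p == pytest.approx(0.8)
        assert r == pytest.approx(8 / 12)
        assert f1 == pytest.approx(2 * 0.8 * (8 / 12) / (0.8 + 8 / 12))

    def test_degenerate_warns(self):
        with pytest.warns(UserWarning):
            p, r, f1 = precision_recall_f1(MatchCounts(tp=0, fp=0, fn=3))
        assert (p, f1) == (0.0, 0.0)

    def test_f1_below_arithmetic_mean(self, rng):
        for _ in range(200):
            p, r = rng.random(2)
            assert f1_from_precision_recall(p, r) <= (p + r) / 2 + 1e-12

    def test_f1_equals_p_when_p_equals_r(self):
        assert f1_from_precision_recall(0.7, 0.7) == pytest.approx(0.7)


class TestAccuracy:
    def test_perfect(self):
        assert accuracy(MatchCounts(tp=10, tn=10)) == 1.0

    def test_all_wrong(self):
        assert accuracy(MatchCounts(tp=0, fp=10, fn=10, tn=0)) == 0.0

    def test_direct_arithmetic(self):
        assert accuracy(MatchCounts(tp=8, fn=2, tn=5, fp=5)) == pytest.approx(0.65)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(MatchCounts())


class TestMeanAp:
    def test_table1(self):
        assert round_half_up(mean_ap([0.996, 0.963, 0.952])) == 0.970

    def test_table2_yolo(self):
        assert round_half_up(mean_ap([0.522, 0.537, 0.888])) == 0.649

    def test_table2_frcnn(self):
        assert round_half_up(mean_ap([0.628, 0.696, 0.949])) == 0.758

    def test_single_class(self):
        assert mean_ap([0.42]) == 0.42

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_ap([])

    def test_linearity(self, rng):
        aps = rng.random(5)
        assert mean_ap(aps) == pytest.approx(aps.sum() / 5)


def _random_instance(rng, n_pred=None, n_truth=None, classes=("a", "b")):
    n_pred = int(rng.integers(0, 10)) if n_pred is None else n_pred
    n_truth = int(rng.integers(1, 10)) if n_truth is None else n_truth

    def rand_box():
        x0, y0 = rng.integers(0, 20, 2)
        return BoundingBox(x0, y0, x0 + rng.integers(3, 10), y0 + rng.integers(3, 10))

    preds = [
        (rand_box(), classes[rng.integers(len(classes))], float(np.round(rng.random(), 3)))
        for _ in range(n_pred)
    ]
    truths = [(classes[rng.integers(len(classes))], rand_box()) for _ in range(n_truth)]
    return preds, truths


def brute_force_match(preds, truths, thr):
    """Greedy matching oracle: process predictions in explicit confidence
    order, scanning all truths each time."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][2], i))
    used = set()
    tp = 0
    for i in order:
        box, label, _ = preds[i]
        best, best_v = None, 0.0
        for j, (t_label, t_box) in enumerate(truths):
            if j in used or t_label != label:
                continue
            v = brute_force_iou(box, t_box)
            if v >= thr and v > best_v:
                best, best_v = j, v
        if best is not None:
            used.add(best)
            tp += 1
    return tp, len(preds) - tp, len(truths) - len(used)


class TestMatchDetections:
    def test_perfect_predictions(self):
        truths = [("a", BoundingBox(0, 0, 5, 5)), ("b", BoundingBox(8, 8, 12, 12))]
        preds = [(b, l, 0.9) for l, b in truths]
        counts, _ = match_detections(preds, truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)

    def test_no_predictions(self):
        truths = [("a", BoundingBox(0, 0, 5, 5))]
        counts, _ = match_detections([], truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 1)

    def test_three_preds_two_truths_hand_case(self):
        truths = [("a", BoundingBox(0, 0, 10, 10)), ("a", BoundingBox(20, 0, 30, 10))]
        preds = [
            (BoundingBox(1, 0, 11, 10), "a", 0.9),   # matches truth 0
            (BoundingBox(0, 0, 10, 10), "a", 0.8),   # truth 0 taken -> FP
            (BoundingBox(21, 0, 31, 10), "a", 0.7),  # matches truth 1
        ]
        counts, assignment = match_detections(preds, truths, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (2, 1, 0)
        assert assignment[0][1] == 0 and assignment[2][1] == 1
        assert assignment[1][1] is None

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            preds, truths = _random_instance(rng)
            counts, _ = match_detections(preds, truths, 0.5)
            assert (counts.tp, counts.fp, counts.fn) == brute_force_match(preds, truths, 0.5)


def brute_force_ap(preds_by_image, truths_by_image, label, thr):
    """Exhaustive threshold-sweep AP oracle with a step-function envelope."""
    confs = sorted(
        {c for preds in preds_by_image.values() for _b, l, c in preds if l == label},
        reverse=True,
    )
    n_truth = sum(1 for t in truths_by_image.values() for l, _ in t if l == label)
    points = [(0.0, 1.0)]
    for cut in confs:
        tp = fp = 0
        for img in truths_by_image:
            preds = [
                p for p in preds_by_image.get(img, []) if p[1] == label and p[2] >= cut
            ]
            t, f, _ = brute_force_match(
                preds, [t for t in truths_by_image[img] if t[0] == label], thr
            )
            tp += t
            fp += f
        points.append((tp / n_truth, tp / max(tp + fp, 1)))
    ap = 0.0
    for k in range(1, len(points)):
        r0, r1 = points[k - 1][0], points[k][0]
        ap += (r1 - r0) * max(p for r, p in points[k:])
    return ap


class TestPrCurveAndAp:
    def test_all_correct(self):
        truths = {0: [("a", BoundingBox(0, 0, 5, 5)), ("a", BoundingBox(10, 10, 15, 15))]}
        preds = {0: [(BoundingBox(0, 0, 5, 5), "a", 0.7), (BoundingBox(10, 10, 15, 15), "a", 0.3)]}
        _curve, ap = pr_curve_and_ap(preds, truths, "a")
        assert ap == 1.0

    def test_single_wrong_prediction(self):
        truths = {0: [("a", BoundingBox(0, 0, 5, 5))]}
        preds = {0: [(BoundingBox(30, 30, 35, 35), "a", 0.9)]}
        _curve, ap = pr_curve_and_ap(preds, truths, "a")
        assert ap == 0.0

    def test_interleaved_hand_case(self):
        truths = {0: [("a", BoundingBox(0, 0, 10, 10)), ("a", BoundingBox(20, 20, 30, 30))]}
        preds = {
            0: [
                (BoundingBox(0, 0, 10, 10), "a", 0.9),    # TP
                (BoundingBox(40, 40, 50, 50), "a", 0.8),  # FP
                (BoundingBox(20, 20, 30, 30), "a", 0.7),  # TP
                (BoundingBox(60, 60, 70, 70), "a", 0.6),  # FP
            ]
        }
        _curve, ap = pr_curve_and_ap(preds, truths, "a")
        assert ap == pytest.approx(brute_force_ap(preds, truths, "a", 0.5))
        # envelope by hand: recall 0.5 at precision 1, recall 1.0 at 2/3
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_no_truths_warns(self):
        with pytest.warns(UserWarning):
            _curve, ap = pr_curve_and_ap({0: []}, {0: []}, "a")
        assert ap is None

    def test_confidence_rescaling_invariance(self, rng):
        preds, truths = _random_instance(rng, n_pred=8, n_truth=5)
        p1 = {0: preds}
        p2 = {0: [(b, l, c * 0.5) for b, l, c in preds]}
        t = {0: truths}
        _c1, ap1 = pr_curve_and_ap(p1, t, "a")
        _c2, ap2 = pr_curve_and_ap(p2, t, "a")
        assert ap1 == pytest.approx(ap2)

    def test_random_instances_match_sweep_oracle(self, rng):
        checked = 0
        for _ in range(100):
            preds, truths = _random_instance(rng)
            if not any(l == "a" for l, _ in truths):
                continue
            p, t = {0: preds}, {0: truths}
            _curve, ap = pr_curve_and_ap(p, t, "a")
            assert ap == pytest.approx(brute_force_ap(p, t, "a", 0.5))
            checked += 1
        assert checked > 50


class TestConfusionMatrix:
    def test_perfect_diagonal(self):
        m = confusion_matrix(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        np.testing.assert_array_equal(m, [[2, 0], [0, 1]])

    def test_single_column(self):
        m = confusion_matrix(["a", "b", "b"], ["a", "a", "a"], ["a", "b"])
        np.testing.assert_array_equal(m, [[1, 0], [2, 0]])

    def test_manual_tally(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "a", "c"]
        m = confusion_matrix(y_true, y_pred, ["a", "b", "c"])
        np.testing.assert_array_equal(m, [[1, 1, 0], [0, 2, 0], [1, 0, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["a"], ["z"], ["a", "b"])


class TestMeanIoU:
    def test_all_ones(self):
        assert mean_iou([[1.0, 1.0], [1.0]]) == 1.0

    def test_single_image_mean(self):
        assert mean_iou([[0.8, 0.6]]) == pytest.approx(0.7)

    def test_per_image_then_across(self):
        # image means: 0.5 and 0.9 -> 0.7; global mean: (0.4+0.6+0.9)/3
        got = mean_iou([[0.4, 0.6], [0.9]])
        assert got == pytest.approx((0.5 + 0.9) / 2)
        assert mean_iou([[0.4, 0.6], [0.9]], per_image=False) == pytest.approx(
            (0.4 + 0.6 + 0.9) / 3
        )

    def test_no_matches_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(mean_iou([[], []]))


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.9605) == 0.961
        assert round_half_up(0.6205) == 0.621

    def test_plain(self):
        assert round_half_up(0.97033) == 0.970


class TestEvaluationReport:
    def test_report_on_clean_detections(self):
        truths = {
            "i0": [("a", BoundingBox(0, 0, 10, 10)), ("b", BoundingBox(20, 20, 28, 28))],
            "i1": [("a", BoundingBox(5, 5, 15, 15))],
        }
        preds = {
            "i0": [
                (BoundingBox(0, 0, 10, 10), "a", 0.9),
                (BoundingBox(20, 20, 28, 28), "b", 0.8),
            ],
            "i1": [(BoundingBox(5, 5, 15, 15), "a", 0.95)],
        }
        report = evaluate_detections(preds, truths, ["a", "b"])
        assert report.map == pytest.approx(1.0)
        assert report.miou == pytest.approx(1.0)
        assert report.per_class["a"]["f1"] == pytest.approx(1.0)
        np.testing.assert_array_equal(report.confusion, [[2, 0], [0, 1]])
        assert "mAP" in report.to_table().splitlines()[0]
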