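"""Segmentation metrics against brute-force oracles on tiny fixtures."""

import numpy as np
import pytest

from caucseg.metrics import (
    ConfusionTally,
    accuracy,
    cce_loss,
    confusion,
    evaluate_predictions,
    f1,
    mean_iou,
    mean_response_time,
    per_class_iou,
    precision,
    recall,
)


def brute_force_tally(pred, truth, m=5):
    """O(HW * M) double-loop oracle for the one-vs-rest confusion counts."""
    tp = np.zeros(m, dtype=np.int64)
    fp = np.zeros(m, dtype=np.int64)
    fn = np.zeros(m, dtype=np.int64)
    tn = np.zeros(m, dtype=np.int64)
    for p, t in zip(np.ravel(pred), np.ravel(truth)):
        for c in range(m):
            if p == c and t == c:
                tp[c] += 1
            elif p == c and t != c:
                fp[c] += 1
            elif p != c and t == c:
                fn[c] += 1
            else:
                tn[c] += 1
    return tp, fp, fn, tn


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        truth = np.random.default_rng(0).integers(0, 5, size=(2, 8, 8))
        t = confusion(truth, truth)
        assert (t.fp == 0).all() and (t.fn == 0).all()

    def test_single_pixel_case(self):
        t = confusion(np.array([[0]]), np.array([[3]]))
        assert t.fp[0] == 1 and t.fn[3] == 1
        assert t.tn[1] == t.tn[2] == t.tn[4] == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        pred = rng.integers(0, 5, size=(8, 8))
        truth = rng.integers(0, 5, size=(8, 8))
        t = confusion(pred, truth)
        tp, fp, fn, tn = brute_force_tally(pred, truth)
        assert (t.tp == tp).all() and (t.fp == fp).all()
        assert (t.fn == fn).all() and (t.tn == tn).all()

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(2)
        pred = rng.integers(0, 5, size=(3, 6, 6))
        truth = rng.integers(0, 5, size=(3, 6, 6))
        t = confusion(pred, truth)
        assert ((t.tp + t.fp + t.fn + t.tn) == pred.size).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(np.zeros((2, 2), int), np.zeros((3, 3), int))


class TestRates:
    def test_perfect_prediction_all_ones_in_every_mode(self):
        truth = np.random.default_rng(3).integers(0, 5, size=(8, 8))
        t = confusion(truth, truth)
        for mode in ("micro", "macro"):
            for fn_ in (accuracy, precision, recall, f1):
                assert fn_(t, mode) == 1.0

    def test_micro_accuracy_equals_micro_precision_and_recall(self):
        rng = np.random.default_rng(4)
        t = confusion(rng.integers(0, 5, size=(10, 10)), rng.integers(0, 5, size=(10, 10)))
        assert accuracy(t) == precision(t) == recall(t)

    def test_f1_is_harmonic_mean_to_1e12(self):
        rng = np.random.default_rng(5)
        t = confusion(rng.integers(0, 5, size=(10, 10)), rng.integers(0, 5, size=(10, 10)))
        for mode in ("micro", "macro"):
            p, r = precision(t, mode), recall(t, mode)
            assert abs(f1(t, mode) - 2 * p * r / (p + r)) < 1e-12
        pc, rc = precision(t, "per_class"), recall(t, "per_class")
        expected = np.where(pc + rc > 0, 2 * pc * rc / np.maximum(pc + rc, 1e-300), 0)
        assert np.abs(f1(t, "per_class") - expected).max() < 1e-12

    def test_headline_precision_recall_consistent_with_f1(self):
        # A precision of 0.9711 and recall of 0.9690 combine to F1 ~ 0.97005.
        p, r = 0.9711, 0.9690
        assert 2 * p * r / (p + r) == pytest.approx(0.97004, abs=1e-5)

    def test_zero_denominator_defined_as_zero_with_warning(self):
        t = confusion(np.array([[0]]), np.array([[3]]))
        with pytest.warns(UserWarning, match="zero denominator"):
            assert precision(t, "per_class")[1] == 0.0
        with pytest.warns(UserWarning):
            assert precision(t, "per_class")[0] == 0.0  # class-0 precision 0


class TestCce:
    def test_perfect_onehot_prediction_is_zero(self):
        y = np.eye(5)[np.random.default_rng(6).integers(0, 5, size=(4, 4))]
        assert cce_loss(y, y) == pytest.approx(0.0, abs=2e-7 * np.log(1e7))

    def test_uniform_prediction_gives_log_m(self):
        y = np.eye(5)[np.random.default_rng(7).integers(0, 5, size=(4, 4))]
        p = np.full_like(y, 0.2)
        assert cce_loss(p, y) == pytest.approx(np.log(5), rel=1e-12)

    def test_two_pixel_fixture_matches_hand_computation(self):
        p = np.array([[[0.7, 0.1, 0.1, 0.05, 0.05],
                       [0.25, 0.25, 0.25, 0.125, 0.125]]])
        y = np.array([[[1, 0, 0, 0, 0],
                       [0, 0, 0, 1, 0]]], dtype=float)
        hand = -(np.log(0.7) + np.log(0.125)) / 2
        assert cce_loss(p, y) == pytest.approx(hand, rel=1e-12)


class TestMiou:
    def test_perfect_prediction_is_one(self):
        truth = np.random.default_rng(8).integers(0, 5, size=(6, 6))
        assert mean_iou(truth, truth) == 1.0

    def test_disjoint_class_has_zero_iou(self):
        pred = np.zeros((4, 4), int)
        truth = np.full((4, 4), 3)
        assert per_class_iou(pred, truth)[0] == 0.0
        assert per_class_iou(pred, truth)[3] == 0.0

    def test_4x4_fixture_matches_set_oracle(self):
        rng = np.random.default_rng(9)
        pred = rng.integers(0, 5, size=(4, 4))
        truth = rng.integers(0, 5, size=(4, 4))
        ious = []
        for c in range(5):
            inter = ((pred == c) & (truth == c)).sum()
            union = ((pred == c) | (truth == c)).sum()
            if union:
                ious.append(inter / union)
        assert mean_iou(pred, truth) == pytest.approx(np.mean(ious), rel=1e-12)

    def test_absent_classes_excluded(self):
        pred = np.zeros((4, 4), int)
        truth = np.zeros((4, 4), int)
        assert mean_iou(pred, truth) == 1.0  # only class 0 participates

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_iou(np.zeros((0,), int), np.zeros((0,), int))


def test_mean_response_time_nonnegative_with_variance():
    from caucseg.model import build_variant

    model = build_variant("V2", input_size=32)
    batch = np.random.default_rng(0).random((2, 32, 32, 3)).astype(np.float32)
    mrt, var = mean_response_time(model, batch, repeats=2)
    assert mrt >= 0 and var >= 0
    single, var0 = mean_response_time(model, batch, repeats=1)
    assert single >= 0 and var0 == 0.0


def test_evaluate_predictions_report_fields():
    rng = np.random.default_rng(10)
    truth = rng.integers(0, 5, size=(2, 8, 8))
    probs = np.eye(5)[truth] * 0.8 + 0.04
    report = evaluate_predictions(probs, truth, npm=123)
    assert report.accuracy_micro == 1.0 and report.miou == 1.0
    assert report.npm == 123
    assert report.f1_micro == pytest.approx(
        2 * report.precision_micro * report.recall_micro
        / (report.precision_micro + report.recall_micro))
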