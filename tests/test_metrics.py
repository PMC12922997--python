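"""Metric correctness against hand values and independent oracles."""

import math

import numpy as np
import pytest

from dolphinseg.metrics import (
    ConfusionCounts,
    accuracy,
    confusion_counts,
    dice_loss,
    dsc,
    evaluate_pair,
    hausdorff,
    jsi,
    precision_recall_f1,
)

from conftest import random_mask_pair


# -- independent brute-force oracles (pixel loops / pairwise distances) ------

def _loop_counts(pred, truth):
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def _pairwise_hausdorff(pred, truth):
    a = [(i, j) for i, j in zip(*np.nonzero(pred))]
    b = [(i, j) for i, j in zip(*np.nonzero(truth))]
    d_ab = max(min(math.dist(p, q) for q in b) for p in a)
    d_ba = max(min(math.dist(p, q) for q in a) for p in b)
    return max(d_ab, d_ba)


class TestConfusionCounts:
    def test_identity_and_complement(self):
        ones = np.ones((2, 2), dtype=int)
        zeros = np.zeros((2, 2), dtype=int)
        c = confusion_counts(ones, ones)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 0, 0, 0)
        c = confusion_counts(zeros, ones)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 0, 4)

    def test_mixed_pair_by_hand(self):
        pred = np.array([[1, 1], [0, 0]])
        truth = np.array([[1, 0], [1, 0]])
        c = confusion_counts(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(3, 3\)"):
            confusion_counts(np.zeros((2, 2), int), np.zeros((3, 3), int))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion_counts(np.array([[2, 0]]), np.array([[1, 0]]))


@pytest.mark.parametrize(
    "counts,expect_dsc,expect_jsi",
    [
        (ConfusionCounts(5, 0, 0, 0), 100.0, 100.0),
        (ConfusionCounts(0, 0, 3, 4), 0.0, 0.0),
        (ConfusionCounts(2, 0, 1, 1), 200.0 / 3.0, 50.0),
        (ConfusionCounts(0, 9, 0, 0), 100.0, 100.0),  # empty-against-empty
    ],
)
def test_overlap_scores_hand_values(counts, expect_dsc, expect_jsi):
    assert dsc(counts) == pytest.approx(expect_dsc, abs=1e-12)
    assert jsi(counts) == pytest.approx(expect_jsi, abs=1e-12)


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(4, 0, 0, 0), 100.0),
        (ConfusionCounts(0, 0, 2, 2), 0.0),
        (ConfusionCounts(2, 10, 1, 1), 1200.0 / 14.0),
    ],
)
def test_accuracy_hand_values(counts, expected):
    assert accuracy(counts) == pytest.approx(expected, abs=1e-12)


def test_accuracy_zero_pixels_is_error():
    with pytest.raises(ValueError):
        accuracy(ConfusionCounts(0, 0, 0, 0))


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(2, 0, 1, 1), (200.0 / 3, 200.0 / 3, 200.0 / 3)),
        (ConfusionCounts(3, 0, 0, 0), (100.0, 100.0, 100.0)),
        (ConfusionCounts(0, 0, 5, 5), (0.0, 0.0, 0.0)),
    ],
)
def test_precision_recall_f1_hand_values(counts, expected):
    assert precision_recall_f1(counts) == pytest.approx(expected, abs=1e-9)


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = np.zeros((5, 5), int)
        m[1:3, 2:4] = 1
        assert hausdorff(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((5, 6), int)
        b = np.zeros((5, 6), int)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(a, b) == pytest.approx(5.0)

    def test_superset_extra_pixel(self):
        truth = np.zeros((6, 6), int)
        truth[2:4, 2:4] = 1
        pred = truth.copy()
        pred[2, 5] = 1  # distance 2 from (2,3)
        assert hausdorff(pred, truth) == pytest.approx(2.0)

    def test_empty_mask_gives_inf_with_warning(self):
        m = np.zeros((4, 4), int)
        full = np.ones((4, 4), int)
        with pytest.warns(UserWarning):
            assert hausdorff(m, full) == math.inf


class TestDiceLoss:
    def test_identity_near_zero(self):
        t = np.zeros((4, 4), int)
        t[:2] = 1
        assert dice_loss(t.astype(float), t) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_near_one(self):
        a = np.zeros((10, 10), int)
        b = np.zeros((10, 10), int)
        a[:5] = 1
        b[5:] = 1
        assert dice_loss(a.astype(float), b, eps=1e-6) == pytest.approx(1.0, abs=1e-3)

    def test_half_overlap_formula(self):
        # sum(Y)=4, sum(P)=4, sum(YP)=2, eps=0 -> 1 - 4/8 = 0.5
        truth = np.array([[1, 1, 1, 1, 0, 0]])
        pred = np.array([[1.0, 1.0, 0.0, 0.0, 1.0, 1.0]])
        assert dice_loss(pred, truth, eps=0.0) == pytest.approx(0.5)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.array([[1.5]]), np.array([[1]]))


class TestOracleEquivalence:
    """All scalar metrics must match brute-force oracles on random pairs."""

    def test_counts_and_scores_match_loops(self, rng):
        for _ in range(50):
            pred, truth = random_mask_pair(rng)
            c = confusion_counts(pred, truth)
            assert (c.tp, c.tn, c.fp, c.fn) == _loop_counts(pred, truth)
            tp, _, fp, fn = _loop_counts(pred, truth)
            if tp + fp + fn:
                assert dsc(c) == pytest.approx(200.0 * tp / (fp + 2 * tp + fn), abs=1e-9)
                assert jsi(c) == pytest.approx(100.0 * tp / (tp + fp + fn), abs=1e-9)

    def test_hausdorff_matches_pairwise(self, rng):
        for _ in range(20):
            pred, truth = random_mask_pair(rng, shape=(9, 9))
            if pred.sum() == 0 or truth.sum() == 0:
                continue
            assert hausdorff(pred, truth) == pytest.approx(
                _pairwise_hausdorff(pred, truth), abs=1e-9
            )

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import f1_score, jaccard_score, precision_score, recall_score

        for _ in range(20):
            pred, truth = random_mask_pair(rng)
            c = confusion_counts(pred, truth)
            p, r, f1 = precision_recall_f1(c)
            yp, yt = pred.ravel(), truth.ravel()
            assert p == pytest.approx(100 * precision_score(yt, yp, zero_division=1), abs=1e-9)
            assert r == pytest.approx(100 * recall_score(yt, yp, zero_division=1), abs=1e-9)
            assert f1 == pytest.approx(100 * f1_score(yt, yp, zero_division=1), abs=1e-9)
            assert jsi(c) == pytest.approx(100 * jaccard_score(yt, yp, zero_division=1), abs=1e-9)


class TestIdentitiesAndSymmetry:
    def test_dsc_jsi_identity_and_f1(self, rng):
        for _ in range(100):
            pred, truth = random_mask_pair(rng, shape=(8, 8))
            c = confusion_counts(pred, truth)
            j = jsi(c)
            assert dsc(c) == pytest.approx(200.0 * j / (100.0 + j), abs=1e-9)
            assert dsc(c) >= j - 1e-12
            assert precision_recall_f1(c)[2] == pytest.approx(dsc(c), abs=1e-9)

    def test_symmetry_and_ranges(self, rng):
        for _ in range(30):
            pred, truth = random_mask_pair(rng)
            rep_ab = evaluate_pair(pred, truth)
            rep_ba = evaluate_pair(truth, pred)
            assert rep_ab.dsc_pct == pytest.approx(rep_ba.dsc_pct, abs=1e-12)
            assert rep_ab.hausdorff_px == pytest.approx(rep_ba.hausdorff_px, abs=1e-12)
            for v in (rep_ab.dsc_pct, rep_ab.jsi_pct, rep_ab.accuracy_pct,
                      rep_ab.precision_pct, rep_ab.recall_pct, rep_ab.f1_pct):
                assert 0.0 <= v <= 100.0
            assert rep_ab.hausdorff_px >= 0.0

    def test_hausdorff_zero_iff_equal_foreground(self, rng):
        pred, truth = random_mask_pair(rng)
        if pred.sum() and truth.sum() and not np.array_equal(pred, truth):
            assert hausdorff(pred, truth) > 0
        m = (rng.random((6, 6)) < 0.5).astype(int)
        if m.sum():
            assert hausdorff(m, m) == 0.0
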