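"""Evaluation mathematics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from aprnet import metrics

from _oracles import (
    exhaustive_youden,
    pairwise_auc,
    random_scored_instance as _random_instance,
    sov_oracle,
    threshold_sweep_ap,
)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestConfusion:
    def test_identity_prediction(self):
        c = metrics.confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_inverted_prediction(self):
        c = metrics.confusion([0, 0, 1, 1], [1, 1, 0, 0])
        assert (c.TP, c.TN) == (0, 0)
        assert (c.FP, c.FN) == (2, 2)

    def test_matches_brute_force_tally(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            pred = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            c = metrics.confusion(pred, truth)
            tally = {"TP": 0, "FP": 0, "FN": 0, "TN": 0}
            for p, t in zip(pred, truth):
                key = ("T" if p == t else "F") + ("P" if p == 1 else "N")
                tally[key] += 1
            assert (c.TP, c.FP, c.FN, c.TN) == (
                tally["TP"], tally["FP"], tally["FN"], tally["TN"])
            assert c.total == n

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            metrics.confusion([1, 0], [1])


class TestRatioMetrics:
    def test_worked_example(self):
        prec, rec, spec = metrics.precision_recall_specificity(
            metrics.ConfusionCounts(TP=3, FP=1, FN=1, TN=5))
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.75)
        assert spec == pytest.approx(5 / 6)

    def test_zero_denominator_flagged_nan(self):
        prec, rec, spec = metrics.precision_recall_specificity(
            metrics.ConfusionCounts(TP=0, FP=0, FN=2, TN=3))
        assert math.isnan(prec)
        assert rec == 0.0
        assert spec == 1.0

    def test_perfect_classifier(self):
        prec, rec, spec = metrics.precision_recall_specificity(
            metrics.ConfusionCounts(TP=4, FP=0, FN=0, TN=6))
        assert (prec, rec, spec) == (1.0, 1.0, 1.0)

    def test_random_counts_match_definitions(self, rng):
        for _ in range(100):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 10, 4))
            c = metrics.ConfusionCounts(tp, fp, fn, tn)
            prec, rec, spec = metrics.precision_recall_specificity(c)
            for got, num, den in ((prec, tp, tp + fp), (rec, tp, tp + fn),
                                  (spec, tn, fp + tn)):
                if den == 0:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(num / den)


class TestROC:
    def test_perfect_separation(self):
        roc = metrics.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_constant_scores_uninformative(self):
        roc = metrics.roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_known_pairwise_value(self):
        roc = metrics.roc_curve([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            metrics.roc_curve([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("discretize", [False, True])
    def test_trapezoid_equals_pairwise_statistic(self, rng, discretize):
        for _ in range(200):
            scores, truth = _random_instance(rng, discretize=discretize)
            roc = metrics.roc_curve(scores, truth)
            assert abs(roc.auc - pairwise_auc(scores, truth)) < 1e-12


class TestPR:
    def test_perfect_separation(self):
        pr = metrics.pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert pr.auc == pytest.approx(1.0)

    def test_constant_scores_equal_prevalence(self):
        pr = metrics.pr_curve([0.3] * 8, [1, 0, 0, 0, 1, 0, 0, 0])
        assert pr.auc == pytest.approx(0.25)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            metrics.pr_curve([0.1, 0.9], [0, 0])

    @pytest.mark.parametrize("discretize", [False, True])
    def test_matches_threshold_sweep_oracle(self, rng, discretize):
        for _ in range(200):
            scores, truth = _random_instance(rng, n_max=30, discretize=discretize)
            if truth.sum() == 0:
                continue
            pr = metrics.pr_curve(scores, truth)
            assert pr.auc == pytest.approx(
                threshold_sweep_ap(list(scores), truth), abs=1e-12)


class TestYouden:
    def test_perfect_separator_unit_j(self):
        roc = metrics.roc_curve([0.9, 0.8, 0.5, 0.3], [1, 1, 0, 0])
        thr, j = metrics.youden_threshold(roc)
        assert j == pytest.approx(1.0)
        # smallest qualifying candidate threshold: the lowest positive score
        assert thr == pytest.approx(0.8)

    def test_uninformative_zero_j(self):
        roc = metrics.roc_curve([0.4] * 6, [1, 0, 1, 0, 1, 0])
        _, j = metrics.youden_threshold(roc)
        assert j == pytest.approx(0.0)

    def test_worked_instance_matches_exhaustive_search(self):
        scores = [0.9, 0.8, 0.4, 0.5, 0.3, 0.1]
        truth = [1, 1, 1, 0, 0, 0]
        roc = metrics.roc_curve(scores, truth)
        thr, j = metrics.youden_threshold(roc)
        assert j == pytest.approx(exhaustive_youden(scores, truth), abs=1e-12)
        # the returned threshold achieves that J
        pred = [1 if s >= thr else 0 for s in scores]
        c = metrics.confusion(pred, truth)
        _, rec, spec = metrics.precision_recall_specificity(c)
        assert rec + spec - 1 == pytest.approx(j, abs=1e-12)

    def test_random_instances_match_exhaustive(self, rng):
        for _ in range(200):
            scores, truth = _random_instance(rng, n_max=25, discretize=True)
            roc = metrics.roc_curve(scores, truth)
            thr, j = metrics.youden_threshold(roc)
            assert j == pytest.approx(exhaustive_youden(list(scores), list(truth)),
                                      abs=1e-12)
            pred = (scores >= thr).astype(int)
            _, rec, spec = metrics.precision_recall_specificity(
                metrics.confusion(pred, truth))
            assert rec + spec - 1 == pytest.approx(j, abs=1e-12)


class TestSOV:
    def test_identical_segmentations_score_100(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            res = metrics.sov_both(labels, labels)
            assert res.sov_apr == pytest.approx(100.0)
            assert res.sov_non_apr == pytest.approx(100.0)

    def test_disjoint_segments_score_0(self):
        truth = [1] * 5 + [0] * 15
        pred = [0] * 15 + [1] * 5
        assert metrics.sov(pred, truth, positive=True) == pytest.approx(0.0)

    def test_partial_overlap_pinned_case(self):
        # truth APR at 10-20, prediction at 15-25 (1-based) on length 30:
        # minov 6, maxov 16, delta min(10,6,5,5)=5 -> 100*(6+5)/16 = 68.75
        truth = np.zeros(30, dtype=int)
        truth[9:20] = 1
        pred = np.zeros(30, dtype=int)
        pred[14:25] = 1
        res = metrics.sov_both(pred, truth)
        assert res.sov_apr == pytest.approx(68.75)
        # non-APR: pairs (1-9 vs 1-14) and (21-30 vs 26-30)
        expected = 100.0 * (9 * 13 / 14 + 10 * 7 / 10) / 19
        assert res.sov_non_apr == pytest.approx(expected)
        assert res.sov_apr == pytest.approx(sov_oracle(list(pred), list(truth), 1))
        assert res.sov_non_apr == pytest.approx(sov_oracle(list(pred), list(truth), 0))

    def test_random_segmentations_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            pred = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            for target, positive in ((1, True), (0, False)):
                got = metrics.sov(pred, truth, positive=positive)
                want = sov_oracle(list(pred), list(truth), target)
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)
                    assert 0.0 <= got <= 100.0

    def test_invariant_to_padding_equal_class_at_ends(self):
        truth = [0, 1, 1, 1, 0, 0, 1, 1, 0]
        pred = [0, 1, 1, 0, 0, 1, 1, 1, 0]
        base = metrics.sov(pred, truth, positive=True)
        padded = metrics.sov([0] * 3 + pred + [0] * 2, [0] * 3 + truth + [0] * 2,
                             positive=True)
        assert padded == pytest.approx(base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            metrics.sov([1, 0], [1, 0, 1])


class TestMacroAverage:
    def test_excludes_nan(self):
        assert metrics.macro_average([1.0, math.nan, 3.0]) == pytest.approx(2.0)

    def test_all_nan_is_nan(self):
        assert math.isnan(metrics.macro_average([math.nan]))
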