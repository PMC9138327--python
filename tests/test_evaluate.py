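"""ROC/PR curves, areas, Youden threshold — against brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score as sk_roc_auc

import dtifusion as dt
from dtifusion.evaluate import ConfusionCounts, EvalError


def mann_whitney_auc(scores, labels) -> float:
    """Rank-statistic oracle: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def confusion_at(scores, labels, t):
    tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
    tn = sum(1 for s, y in zip(scores, labels) if s < t and y == 0)
    return tp, fp, tn, fn


FOUR_POINT = ([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0])


class TestRocPoints:
    def test_perfect_ranking_passes_through_corner(self):
        pts = dt.roc_points([0.9, 0.1], [1, 0])
        assert (0.0, 1.0) in {(fpr, tpr) for _, fpr, tpr in pts}

    def test_constant_scores_give_two_points(self):
        pts = dt.roc_points([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert [(fpr, tpr) for _, fpr, tpr in pts] == [(0.0, 0.0), (1.0, 1.0)]

    def test_matches_per_threshold_confusion_enumeration(self):
        scores, labels = FOUR_POINT
        for t, fpr, tpr in dt.roc_points(scores, labels):
            tp, fp, tn, fn = confusion_at(scores, labels, t)
            assert fpr == fp / 2 and tpr == tp / 2

    def test_fpr_non_decreasing_as_threshold_drops(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        fprs = [fpr for _, fpr, _ in dt.roc_points(scores, labels)]
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(EvalError):
            dt.roc_points([0.1, 0.9], [1, 1])


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert dt.roc_auc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert dt.roc_auc_score([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_four_point_example(self):
        scores, labels = FOUR_POINT
        assert dt.roc_auc_score(scores, labels) == pytest.approx(0.75, abs=1e-12)
        assert mann_whitney_auc(scores, labels) == 0.75

    def test_equals_rank_statistic_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 25))
            scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # force ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            auc = dt.roc_auc_score(scores, labels)
            assert abs(auc - mann_whitney_auc(scores, labels)) < 1e-12
            assert abs(auc - sk_roc_auc(labels, scores)) < 1e-12


class TestPrCurve:
    def test_perfect_separation_aupr_one(self):
        pts = dt.pr_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert dt.aupr(pts) == 1.0

    def test_precision_at_all_positive_threshold_is_prevalence(self):
        scores, labels = [0.9, 0.6, 0.3, 0.1], [1, 0, 0, 0]
        pts = dt.pr_points(scores, labels)
        t_min = min(scores)
        prec = {t: p for t, _, p in pts}[t_min]
        assert prec == 0.25

    def test_matches_enumeration_on_four_point_example(self):
        scores, labels = FOUR_POINT
        for t, recall, precision in dt.pr_points(scores, labels):
            tp, fp, tn, fn = confusion_at(scores, labels, t)
            assert recall == tp / 2
            assert precision == (tp / (tp + fp) if tp + fp else 1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(EvalError):
            dt.pr_points([0.2, 0.8], [0, 0])


class TestOptimalThreshold:
    def test_perfect_pair_picks_positive_score(self):
        pts = dt.roc_points([0.2, 0.9], [0, 1])
        assert dt.optimal_threshold(pts) == 0.9

    def test_constant_scores_return_sentinel(self):
        pts = dt.roc_points([0.5, 0.5], [0, 1])
        assert dt.optimal_threshold(pts) == 1.5

    def test_four_point_example_matches_brute_force(self):
        scores, labels = FOUR_POINT
        pts = dt.roc_points(scores, labels)
        js = {t: tpr - fpr for t, fpr, tpr in pts}
        best = max(sorted(js, reverse=True), key=lambda t: js[t])
        assert dt.optimal_threshold(pts) == best

    def test_matches_brute_force_argmax_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            pts = dt.roc_points(scores, labels)
            best_j = max(tpr - fpr for _, fpr, tpr in pts)
            candidates = [t for t, fpr, tpr in pts if tpr - fpr == best_j]
            assert dt.optimal_threshold(pts) == max(candidates)


class TestThresholdedMetrics:
    def test_worked_confusion_example(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.2, 0.7, 0.3, 0.1]
        counts, acc, f1, precision, recall = dt.thresholded_metrics(scores, labels, 0.6)
        assert counts == ConfusionCounts(tp=2, fp=1, tn=2, fn=1)
        assert acc == pytest.approx(4 / 6)
        assert precision == pytest.approx(2 / 3)
        assert recall == pytest.approx(2 / 3)
        assert f1 == pytest.approx(2 / 3)

    def test_threshold_below_min_predicts_everything_positive(self):
        labels = [1, 0, 0, 1]
        scores = [0.4, 0.3, 0.2, 0.6]
        counts, acc, f1, precision, recall = dt.thresholded_metrics(scores, labels, 0.0)
        assert recall == 1.0
        assert precision == 0.5  # prevalence

    def test_threshold_above_max_gives_f1_zero(self):
        counts, acc, f1, precision, recall = dt.thresholded_metrics(
            [0.2, 0.4], [0, 1], 0.9
        )
        assert counts.tp == 0 and counts.fp == 0
        assert f1 == 0.0

    def test_confusion_totals(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        counts, *_ = dt.thresholded_metrics(scores, labels, 0.5)
        assert counts.total == 40


class TestInvarianceAndReport:
    def test_rank_metrics_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        transformed = np.exp(3 * scores)  # strictly increasing
        assert dt.roc_auc_score(scores, labels) == pytest.approx(
            dt.roc_auc_score(transformed, labels), abs=1e-12)
        assert dt.aupr(dt.pr_points(scores, labels)) == pytest.approx(
            dt.aupr(dt.pr_points(transformed, labels)), abs=1e-12)
        # the chosen threshold sits at the same rank position
        t1 = dt.optimal_threshold(dt.roc_points(scores, labels))
        t2 = dt.optimal_threshold(dt.roc_points(transformed, labels))
        assert (scores >= t1).tolist() == (transformed >= t2).tolist()

    def test_report_is_self_consistent(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        rep = dt.evaluate_scores(scores, labels)
        counts, acc, f1, precision, recall = dt.thresholded_metrics(
            scores, labels, rep.opt_threshold)
        assert rep.confusion == counts and rep.acc == acc and rep.f1 == f1
        assert 0.0 <= rep.auc <= 1.0 and 0.0 <= rep.aupr <= 1.0
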