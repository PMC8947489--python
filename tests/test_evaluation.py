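"""Metric suite: confusion counts, ROC/AUC, log loss, bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slideweak.evaluation import (
    ConfusionCounts,
    ScoredCohort,
    auc,
    auc_score,
    bootstrap_ci,
    confusion_at_threshold,
    fpr,
    log_loss,
    metric_report,
    roc_curve,
    summary_metrics,
    tpr,
)


def cohort_of(labels, scores):
    return ScoredCohort([f"s{i}" for i in range(len(labels))], np.array(labels), np.array(scores))


def pairwise_auc(cohort):
    """Mann-Whitney oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = cohort.scores[cohort.labels == 1]
    neg = cohort.scores[cohort.labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_separated_pair(self):
        c = confusion_at_threshold(cohort_of([1, 0], [0.9, 0.1]), 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_threshold_zero_calls_everything_positive(self):
        c = confusion_at_threshold(cohort_of([1, 0, 0], [0.3, 0.2, 0.0]), 0.0)
        assert c.FN == 0 and c.TN == 0 and c.TP == 1 and c.FP == 2

    def test_threshold_above_max_calls_everything_negative(self):
        c = confusion_at_threshold(cohort_of([1, 0], [0.9, 0.1]), 0.90001)
        assert c.TP == 0 and c.FP == 0 and c.FN == 1 and c.TN == 1

    def test_ties_at_threshold_called_positive(self):
        c = confusion_at_threshold(cohort_of([1, 0], [0.5, 0.5]), 0.5)
        assert c.TP == 1 and c.FP == 1

    def test_counts_sum_to_cohort_size(self):
        c = confusion_at_threshold(cohort_of([1, 0, 1, 0, 1], [0.1, 0.5, 0.9, 0.3, 0.6]), 0.4)
        assert c.total == 5


class TestRates:
    def test_tpr_formula(self):
        assert tpr(ConfusionCounts(TP=3, FP=0, TN=0, FN=1)) == 0.75

    def test_fpr_zero_when_no_false_positives(self):
        assert fpr(ConfusionCounts(TP=0, FP=0, TN=5, FN=0)) == 0.0

    def test_tpr_zero_when_all_missed(self):
        assert tpr(ConfusionCounts(TP=0, FP=0, TN=0, FN=4)) == 0.0

    def test_zero_denominators_raise(self):
        with pytest.raises(ZeroDivisionError, match="positives"):
            tpr(ConfusionCounts(0, 1, 1, 0))
        with pytest.raises(ZeroDivisionError, match="negatives"):
            fpr(ConfusionCounts(1, 0, 0, 1))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        assert auc_score(cohort_of([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])) == pytest.approx(1.0)

    def test_constant_scores_give_chance_auc(self):
        assert auc_score(cohort_of([1, 0, 1, 0], [0.5] * 4)) == pytest.approx(0.5)

    def test_single_label_cohort_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            roc_curve(cohort_of([1, 1], [0.2, 0.4]))

    def test_curve_spans_both_corners(self, rng):
        c = cohort_of(rng.integers(2, size=20), rng.random(20))
        f, t, thr = roc_curve(c)
        assert (f[0], t[0]) == (0.0, 0.0) and (f[-1], t[-1]) == (1.0, 1.0)
        assert (np.diff(f) >= 0).all() and (np.diff(t) >= 0).all()

    def test_sweep_matches_confusion_at_each_threshold(self, rng):
        """Dual route: vectorized sweep vs explicit per-threshold counting."""
        labels = rng.integers(2, size=30)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(30), 2)
        c = cohort_of(labels, scores)
        f, t, thr = roc_curve(c)
        for fi, ti, th in zip(f, t, thr):
            cc = confusion_at_threshold(c, th)
            assert fi == pytest.approx(fpr(cc), abs=1e-12)
            assert ti == pytest.approx(tpr(cc), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = rng.integers(2, size=n)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(n), 1)  # heavy ties
        c = cohort_of(labels, scores)
        assert auc_score(c) == pytest.approx(pairwise_auc(c), abs=1e-9)

    def test_label_swap_score_flip_symmetry(self, rng):
        labels = rng.integers(2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        a = auc_score(cohort_of(labels, scores))
        b = auc_score(cohort_of(1 - labels, 1.0 - scores))
        assert a == pytest.approx(b, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(2, size=50)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(50), 2)
        c = cohort_of(labels, scores)
        assert auc_score(c) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestLogLoss:
    def test_coin_flip(self):
        assert log_loss(cohort_of([1, 0], [0.5, 0.5])) == pytest.approx(np.log(2))

    def test_perfect_clipped(self):
        assert log_loss(cohort_of([1, 0], [1.0, 0.0]), eps=1e-15) < 1e-9

    def test_single_slide_closed_form(self):
        assert log_loss(cohort_of([1], [0.25])) == pytest.approx(-np.log(0.25))


class TestSummaryMetrics:
    def test_textbook_confusion_table(self):
        # TP=45, FN=5, TN=48, FP=2
        labels = [1] * 50 + [0] * 50
        scores = [0.9] * 45 + [0.1] * 5 + [0.1] * 48 + [0.9] * 2
        m = summary_metrics(cohort_of(labels, scores), 0.5)
        assert m["accuracy"] == pytest.approx(0.93)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.96)
        assert m["f1"] == pytest.approx(90 / 97)

    def test_perfect_classifier(self):
        m = summary_metrics(cohort_of([1, 0], [0.9, 0.1]), 0.5)
        assert all(v == 1.0 for v in m.values())

    def test_all_positive_caller_on_balanced_cohort(self):
        m = summary_metrics(cohort_of([1, 0, 1, 0], [0.9] * 4), 0.5)
        assert m["accuracy"] == 0.5 and m["sensitivity"] == 1.0 and m["specificity"] == 0.0


class TestBootstrap:
    def test_constant_statistic_collapses_to_point(self):
        c = cohort_of([1, 0, 1, 0], [0.8, 0.2, 0.7, 0.3])
        lo, hi = bootstrap_ci(c, lambda s: 0.42, n_iter=100, seed=1)
        assert lo == hi == 0.42

    def test_same_seed_identical_interval(self):
        c = cohort_of([1, 0, 1, 0, 1, 0], [0.8, 0.2, 0.7, 0.3, 0.6, 0.4])
        a = bootstrap_ci(c, auc_score, n_iter=200, seed=7)
        b = bootstrap_ci(c, auc_score, n_iter=200, seed=7)
        assert a == b

    def test_interval_brackets_point_for_auc(self, rng):
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        scores = np.clip(np.r_[rng.normal(0.6, 0.15, 30), rng.normal(0.4, 0.15, 30)], 0, 1)
        c = cohort_of(labels, scores)
        lo, hi = bootstrap_ci(c, auc_score, n_iter=400, seed=3)
        assert lo <= auc_score(c) <= hi

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(cohort_of([1], [0.5]), auc_score, n_iter=10, seed=0)


class TestMetricReport:
    def test_report_holds_all_six_metrics_with_cis(self):
        labels = [1] * 20 + [0] * 20
        scores = list(np.linspace(0.55, 0.95, 20)) + list(np.linspace(0.05, 0.45, 20))
        report = metric_report(cohort_of(labels, scores), n_bootstrap=100, seed=0)
        d = report.to_dict()
        for name in ("auc", "log_loss", "accuracy", "sensitivity", "specificity", "f1"):
            assert {"point", "ci_low", "ci_high"} <= set(d[name])
            assert d[name]["ci_low"] <= d[name]["ci_high"]
        assert d["auc"]["point"] == pytest.approx(1.0)
        assert "auc" in report.summary()

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cohort_of([1, 0], [1.2, 0.1])
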