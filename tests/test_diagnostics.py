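"""Confusion metrics, DeLong AUC, Hosmer-Lemeshow calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from conftest import random_cohort
from ipmn_balance import (
    calibration_bins,
    confusion_at_cutoff,
    hosmer_lemeshow,
    roc_auc,
    roc_points,
)


def mann_whitney_auc(labels, scores):
    """O(n^2) all-pairs oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_hand_counted_toy(self, toy4):
        labels, mp = toy4
        d = confusion_at_cutoff(labels, mp, 25)
        assert (d.tp, d.fp, d.tn, d.fn) == (1, 1, 1, 1)
        assert d.sensitivity == d.specificity == d.ppv == d.npv == 0.5
        assert d.n_under_count == 2

    def test_cutoff_below_all_scores_gives_full_sensitivity(self, toy4):
        labels, mp = toy4
        d = confusion_at_cutoff(labels, mp, 5)
        assert d.sensitivity == 1.0
        assert d.npv is None  # nobody under the cutoff: 0/0, flagged not zeroed

    def test_perfect_separation_scores_ones_everywhere(self):
        labels = np.array([0, 0, 1, 1], dtype=bool)
        mp = np.array([0.1, 0.2, 0.8, 0.9])
        d = confusion_at_cutoff(labels, mp, 50)
        assert d.sensitivity == d.specificity == d.ppv == d.npv == 1.0

    def test_degenerate_class_is_flagged_not_silent(self):
        d = confusion_at_cutoff(np.zeros(5, bool), np.full(5, 0.3), 50)
        assert d.sensitivity is None and d.degenerate

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 99))
    def test_margins_conserved_at_every_cutoff(self, seed, cutoff):
        labels, mp = random_cohort(np.random.default_rng(seed))
        d = confusion_at_cutoff(labels, mp, cutoff)
        assert d.tp + d.fn == labels.sum()
        assert d.tn + d.fp == (~labels).sum()
        assert d.n_under_count == d.tn + d.fn


class TestRocAuc:
    def test_perfect_separation_is_unity(self):
        labels = np.array([0, 0, 0, 1, 1], dtype=bool)
        assert roc_auc(labels, np.array([0.1, 0.2, 0.3, 0.8, 0.9])).auc == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_all_pairs_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        labels, _ = random_cohort(rng, n=n)
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        got = roc_auc(labels, scores).auc
        assert got == pytest.approx(mann_whitney_auc(labels, scores), abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        labels, mp = random_cohort(rng, n=500)
        assert roc_auc(labels, mp).auc == pytest.approx(roc_auc_score(labels, mp), abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(7)
        labels, mp = random_cohort(rng, n=300)
        base = roc_auc(labels, mp)
        warped = roc_auc(labels, np.exp(3 * mp))
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)

    def test_uninformative_scores_sit_near_one_half(self):
        rng = np.random.default_rng(11)
        n = 4000
        labels = rng.random(n) < 0.3
        scores = rng.random(n)  # independent of labels
        m, k = labels.sum(), n - labels.sum()
        null_se = np.sqrt((m + k + 1) / (12.0 * m * k))
        assert abs(roc_auc(labels, scores).auc - 0.5) < 3 * null_se

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.ones(5, bool), np.linspace(0, 1, 5))

    def test_ci_contains_point_estimate(self):
        labels, mp = random_cohort(np.random.default_rng(3), n=200)
        res = roc_auc(labels, mp)
        assert res.ci[0] <= res.auc <= res.ci[1]
        assert res.se > 0

    def test_roc_points_span_unit_square(self):
        labels, mp = random_cohort(np.random.default_rng(5), n=100)
        pts = roc_points(labels, mp)
        assert pts.iloc[0][["tpr", "fpr"]].tolist() == [0.0, 0.0]
        assert pts.iloc[-1][["tpr", "fpr"]].tolist() == [1.0, 1.0]


class TestHosmerLemeshow:
    def test_constant_probs_at_event_rate_give_zero_chi2(self):
        labels = np.array([1, 0, 0, 0, 1, 0, 0, 0, 1, 0] * 3, dtype=bool)
        probs = np.full(30, labels.mean())
        res = hosmer_lemeshow(labels, probs, n_bins=5)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_miscalibrated_probabilities_are_rejected(self):
        """A +1 logit shift at n = 20,000 is decisively detected."""
        rng = np.random.default_rng(13)
        p_true = rng.beta(2, 6, 20_000)
        labels = rng.random(20_000) < p_true
        shifted = expit(logit(p_true) + 1.0)
        assert hosmer_lemeshow(labels, shifted, n_bins=10).p_value < 1e-3

    def test_calibrated_probabilities_pass_on_one_draw(self):
        rng = np.random.default_rng(17)
        p_true = rng.beta(2, 6, 20_000)
        labels = rng.random(20_000) < p_true
        res = hosmer_lemeshow(labels, p_true, n_bins=10, df=10)
        assert res.p_value > 0.001

    def test_bins_partition_cohort_and_conserve_events(self):
        rng = np.random.default_rng(19)
        labels, probs = random_cohort(rng, n=500)
        table = calibration_bins(labels, probs, n_bins=10)
        assert table["n"].sum() == 500
        assert table["observed"].sum() == labels.sum()
        assert table["expected"].sum() == pytest.approx(probs.sum())

    def test_equally_spaced_probs_split_evenly(self):
        labels = np.zeros(10, dtype=bool)
        probs = np.linspace(0.05, 0.95, 10)
        table = calibration_bins(labels, probs, n_bins=5)
        assert table["n"].tolist() == [2, 2, 2, 2, 2]

    def test_bin_means_increase_with_bin_index(self):
        rng = np.random.default_rng(23)
        labels, probs = random_cohort(rng, n=400)
        means = calibration_bins(labels, probs, n_bins=8)["mean_pred"]
        assert means.is_monotonic_increasing

    def test_tied_probabilities_stay_in_one_bin(self):
        labels = np.zeros(20, dtype=bool)
        probs = np.array([0.2] * 10 + [0.8] * 10)
        table = calibration_bins(labels, probs, n_bins=10)
        assert len(table) == 2 and table["n"].tolist() == [10, 10]

    def test_cohort_smaller_than_bins_is_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            hosmer_lemeshow(np.array([True, False]), np.array([0.4, 0.5]), n_bins=5)
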