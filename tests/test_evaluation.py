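"""Discrimination and calibration metrics against oracles and closed forms."""

import numpy as np
import pytest
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from heifersim.errors import DomainError
from heifersim.evaluation import (
    binned_residuals_mace,
    calibration_bins,
    confusion_matrix,
    discrimination_metrics,
    exact_binomial_ci,
    hosmer_lemeshow,
    optimal_threshold,
    roc_and_auc,
    unreliability_test,
)


class TestConfusion:
    def test_all_positive_classifier_on_study_prevalence(self):
        # 464 conceiving / 133 failing services, every prediction 0.9
        p = np.full(597, 0.9)
        y = np.array([1.0] * 464 + [0.0] * 133)
        m = confusion_matrix(p, y, 0.5)
        assert (m.tp, m.fp, m.tn, m.fn) == (464, 133, 0, 0)
        rep = discrimination_metrics(m)
        assert rep.sensitivity == 100.0
        assert rep.specificity == 0.0
        assert rep.ppv == pytest.approx(77.72, abs=0.005)
        assert rep.npv == 0.0
        assert rep.accuracy == pytest.approx(77.72, abs=0.005)
        assert rep.mcc == 0.0

    def test_perfect_classifier(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        rep = discrimination_metrics(confusion_matrix(y, y, 0.5))
        assert rep.sensitivity == rep.specificity == rep.accuracy == 100.0
        assert rep.mcc == 1.0

    def test_threshold_above_max_predicts_all_negative(self):
        p = np.array([0.2, 0.4, 0.6])
        m = confusion_matrix(p, np.array([0.0, 1.0, 1.0]), 0.61)
        assert m.tp == 0 and m.fp == 0 and m.tn + m.fn == 3

    def test_mcc_matches_direct_formula(self):
        m = confusion_matrix(
            np.array([0.9] * 4 + [0.1] * 6),
            np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], dtype=float),
            0.5,
        )
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 1, 1, 5)
        expected = (3 * 5 - 1 * 1) / np.sqrt(4 * 4 * 6 * 6)
        assert discrimination_metrics(m).mcc == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            confusion_matrix(np.array([]), np.array([]))


class TestRoc:
    def test_pure_ties_give_half(self):
        p = np.full(50, 0.5)
        y = np.array([1.0] * 30 + [0.0] * 20)
        _, auc = roc_and_auc(p, y)
        assert auc == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        p = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
        y = np.array([1.0] * 10 + [0.0] * 10)
        _, auc = roc_and_auc(p, y)
        assert auc == 1.0

    def test_trapezoid_equals_pairwise_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            p = rng.choice(np.round(rng.random(8), 2), size=n)
            y = (rng.random(n) < 0.6).astype(float)
            if y.min() == y.max():
                continue
            _, auc = roc_and_auc(p, y)
            pos, neg = p[y == 1], p[y == 0]
            diff = pos[:, None] - neg[None, :]
            oracle = float(np.mean((diff > 0) + 0.5 * (diff == 0)))
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        p = rng.random(300)
        y = (rng.random(300) < p).astype(float)
        _, auc = roc_and_auc(p, y)
        assert auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_roc_points_monotone(self, rng):
        p = rng.random(100)
        y = (rng.random(100) < 0.7).astype(float)
        pts, _ = roc_and_auc(p, y)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_and_auc(np.array([0.1, 0.9]), np.array([1.0, 1.0]))


class TestOptimalThreshold:
    def test_equals_exhaustive_search(self, rng):
        p = rng.random(150)
        y = (rng.random(150) < p).astype(float)
        t = optimal_threshold(p, y)
        n_pos, n_neg = y.sum(), (1 - y).sum()

        def j(th):
            pred = p >= th
            return pred[y == 1].sum() / n_pos + (~pred)[y == 0].sum() / n_neg - 1

        best = max(np.unique(p), key=lambda th: (round(j(th), 12), -th))
        assert j(t) == pytest.approx(j(best), abs=1e-12)

    def test_all_equal_scores_return_smallest(self):
        p = np.full(20, 0.4)
        y = np.array([1.0, 0.0] * 10)
        assert optimal_threshold(p, y) == 0.4

    def test_tie_broken_by_smaller_threshold(self):
        p = np.array([0.2, 0.8, 0.2, 0.8])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert optimal_threshold(p, y) == 0.8  # J=1 at 0.8; J=0 at 0.2


class TestHosmerLemeshow:
    def test_exact_agreement_gives_zero_statistic(self):
        p = np.full(100, 0.5)
        y = np.tile([1.0, 0.0], 50)  # every decile observes exactly 50%
        stat, df, pval = hosmer_lemeshow(p, y)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 8
        assert pval == pytest.approx(1.0)

    def test_null_rejection_rate_near_nominal(self, rng):
        # well-specified model refit on each replicate: the g-2 degrees of
        # freedom absorb the two estimated coefficients
        from heifersim.logistic import fit_logistic

        rejections = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=600)
            X = np.column_stack([np.ones(600), x])
            y = (rng.random(600) < expit(1.2 + 0.8 * x)).astype(float)
            p = expit(X @ fit_logistic(X, y).coef)
            _, _, pval = hosmer_lemeshow(p, y)
            rejections += pval < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_grouping_invariant_to_input_order(self, rng):
        p = rng.random(240)
        y = (rng.random(240) < p).astype(float)
        stat1, _, _ = hosmer_lemeshow(p, y)
        perm = rng.permutation(240)
        stat2, _, _ = hosmer_lemeshow(p[perm], y[perm])
        assert stat1 == pytest.approx(stat2, abs=1e-9)

    def test_matches_direct_decile_computation(self, rng):
        p = np.sort(rng.random(200))
        y = (rng.random(200) < p).astype(float)
        stat, _, _ = hosmer_lemeshow(p, y)
        expected = 0.0
        for g in np.array_split(np.arange(200), 10):
            o1, e1, m = y[g].sum(), p[g].sum(), len(g)
            expected += (o1 - e1) ** 2 / e1 + ((m - o1) - (m - e1)) ** 2 / (m - e1)
        assert stat == pytest.approx(expected, abs=1e-8)


class TestCalibrationBins:
    def test_all_successes_closed_form_lower_bound(self):
        # one bin, 10 of 10 successes: exact lower bound is (alpha/2)^(1/10)
        p = np.full(10, 0.97)
        y = np.ones(10)
        bins = calibration_bins(p, y)
        row = bins[bins["count"] > 0].iloc[0]
        assert row["observed_proportion"] == 1.0
        assert row["ci_low"] == pytest.approx(0.025 ** (1 / 10))
        assert row["ci_high"] == 1.0

    def test_clopper_pearson_f_form(self):
        lo, hi = exact_binomial_ci(7, 10)
        # scipy beta quantiles equal the classical F-distribution form
        assert 0 < lo < 0.7 < hi < 1
        assert (lo, hi) == pytest.approx((0.3475, 0.9333), abs=2e-4)

    def test_empty_bin_emitted_and_flagged(self):
        p = np.full(30, 0.97)
        bins = calibration_bins(p, np.ones(30))
        empty = bins[bins["count"] == 0]
        assert len(empty) == 14
        assert not empty["plotted"].any()

    def test_small_bin_not_plotted(self):
        p = np.concatenate([np.full(5, 0.1), np.full(50, 0.9)])
        y = (p > 0.5).astype(float)
        bins = calibration_bins(p, y)
        assert not bins.iloc[1]["plotted"]  # 5 records < 10
        assert bins[bins["count"] == 50]["plotted"].all()

    def test_coverage_of_exact_intervals(self, rng):
        # perfectly calibrated predictions: observed proportions fall inside
        # their bin intervals about 95% of the time
        inside = total = 0
        for _ in range(40):
            p = rng.uniform(0.05, 0.95, 600)
            y = (rng.random(600) < p).astype(float)
            bins = calibration_bins(p, y)
            plotted = bins[bins["plotted"]]
            inside += (
                (plotted["observed_proportion"] >= plotted["ci_low"])
                & (plotted["observed_proportion"] <= plotted["ci_high"])
            ).sum()
            total += len(plotted)
        assert 0.90 <= inside / total <= 1.0


class TestUnreliability:
    def test_statistic_nonnegative(self, rng):
        p = rng.uniform(0.1, 0.9, 300)
        y = (rng.random(300) < p).astype(float)
        stat, _ = unreliability_test(p, y)
        assert stat >= 0

    def test_null_rejection_rate_near_nominal(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            p = expit(rng.normal(1.0, 1.0, 600))
            y = (rng.random(600) < p).astype(float)
            _, pval = unreliability_test(p, y)
            rejections += pval < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_detects_logit_shift(self, rng):
        p_true = expit(rng.normal(0.5, 1.0, 600))
        y = (rng.random(600) < p_true).astype(float)
        p_shifted = expit(logit(p_true) + 0.6)
        _, pval = unreliability_test(p_shifted, y)
        assert pval < 0.05

    def test_constant_probabilities_rejected(self):
        with pytest.raises(DomainError):
            unreliability_test(np.full(50, 0.5), np.zeros(50))


class TestBinnedResidualsMace:
    def test_exact_groupwise_match_gives_zero(self):
        p = np.repeat([0.25, 0.75], 8)
        y = np.concatenate([np.tile([0, 0, 0, 1.0], 2), np.tile([1, 1, 1, 0.0], 2)])
        devs, mace = binned_residuals_mace(p, y, n_groups=2)
        assert mace == pytest.approx(0.0, abs=1e-12)

    def test_single_group_measures_prevalence_gap(self):
        p = np.full(200, 0.8)
        y = np.array([1.0] * 130 + [0.0] * 70)  # prevalence 0.65
        _, mace = binned_residuals_mace(p, y, n_groups=1)
        assert mace == pytest.approx(15.0, abs=1e-9)

    def test_matches_brute_force_group_averages(self, rng):
        p = rng.random(157)
        y = (rng.random(157) < p).astype(float)
        devs, mace = binned_residuals_mace(p, y)
        order = np.argsort(p, kind="stable")
        expected = [np.mean(y[g] - p[g]) for g in np.array_split(order, 12)]
        np.testing.assert_allclose(devs, expected, atol=1e-12)
        assert mace == pytest.approx(100 * np.mean(np.abs(expected)))

    def test_default_group_count_is_sqrt_n(self, rng):
        p = rng.random(100)
        y = (rng.random(100) < p).astype(float)
        devs, _ = binned_residuals_mace(p, y)
        assert len(devs) == 10
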