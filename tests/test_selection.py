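"""Stepwise selection, the linearity check, importance ranking, odds ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

from heifersim.errors import DomainError
from heifersim.logistic import fit_logistic
from heifersim.model import ModelSpec, build_design_matrix
from heifersim.selection import (
    linearity_check,
    odds_ratio_table,
    rank_variable_importance,
    stepwise_select,
)


def selection_data(rng, n=2000, beta_signal=0.8, n_noise=5):
    df = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(n_noise)})
    df["signal"] = rng.normal(size=n)
    eta = -0.4 + beta_signal * df["signal"]
    df["outcome"] = np.where(rng.random(n) < expit(eta), "positive", "negative")
    return df


class TestStepwise:
    def test_informative_term_selected_noise_mostly_excluded(self, rng):
        hits, noise_terms, reps = 0, 0, 8
        for _ in range(reps):
            df = selection_data(rng)
            cands = {c: "continuous" for c in df.columns if c != "outcome"}
            spec = stepwise_select(df, cands)
            hits += "signal" in spec.continuous_terms
            noise_terms += len(set(spec.continuous_terms) - {"signal"})
        assert hits >= int(0.9 * reps)
        # the P<=0.2 retention rule admits each noise term with prob ~0.2
        assert noise_terms / (5 * reps) < 0.35

    def test_all_noise_candidates_usually_give_intercept_only(self, rng):
        selected = 0
        for _ in range(10):
            df = selection_data(rng, beta_signal=0.0).drop(columns="signal")
            cands = {c: "continuous" for c in df.columns if c != "outcome"}
            spec = stepwise_select(df, cands)
            selected += len(spec.terms)
        # expected ~0.2 terms retained per noise candidate
        assert selected / (10 * 5) < 0.4

    def test_deterministic_on_fixed_data(self, rng):
        df = selection_data(rng)
        cands = {c: "continuous" for c in df.columns if c != "outcome"}
        assert stepwise_select(df, cands) == stepwise_select(df, cands)


class TestLinearity:
    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        reps = 100
        for _ in range(reps):
            n = 1500
            x = rng.uniform(400, 600, n)
            df = pd.DataFrame({"age_days": x})
            eta = -3 + 0.008 * x
            df["outcome"] = np.where(rng.random(n) < expit(eta), "positive", "negative")
            p = linearity_check(df, ["age_days"], scale={"age_days": 460})["age_days:log"]
            rejections += p < 0.05
        assert 0.005 <= rejections / reps <= 0.12

    def test_detects_log_curvature_with_high_power(self):
        significant = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n = 2000
            x = rng.uniform(0.5, 3.0, n)
            eta = -1.0 + 2.0 * x * np.log(x)
            df = pd.DataFrame({"x": x})
            df["outcome"] = np.where(rng.random(n) < expit(eta), "positive", "negative")
            significant += linearity_check(df, ["x"])["x:log"] < 0.05
        assert significant >= 4

    def test_constant_covariate_is_degenerate(self):
        df = pd.DataFrame({"x": np.ones(50), "outcome": ["positive", "negative"] * 25})
        with pytest.raises(DomainError):
            linearity_check(df, ["x"])


class TestImportance:
    @pytest.fixture()
    def month_fit(self, cleaned_frame):
        spec = ModelSpec(factor_terms=("month_cat",), continuous_terms=("civ_pta",))
        X, y, names, levels = build_design_matrix(cleaned_frame, spec)
        return fit_logistic(X, y, names=names, spec=spec, levels=levels)

    def test_single_covariate_ranks_first(self, cleaned_frame):
        spec = ModelSpec(continuous_terms=("civ_pta",))
        X, y, names, _ = build_design_matrix(cleaned_frame, spec)
        fit = fit_logistic(X, y, names=names, spec=spec)
        assert rank_variable_importance(fit)["term"].iloc[0] == "civ_pta"

    def test_ranking_equals_direct_z_computation(self, month_fit):
        ranking = rank_variable_importance(month_fit, by="z")
        direct = {
            n: abs(c / s)
            for n, c, s in zip(month_fit.names, month_fit.coef, month_fit.se)
            if n != "(Intercept)"
        }
        expected = [t for t, _ in sorted(direct.items(), key=lambda kv: -kv[1])]
        assert list(ranking["term"]) == expected

    def test_factor_levels_are_separate_entries(self, month_fit):
        terms = set(rank_variable_importance(month_fit)["term"])
        assert {"month_cat:May", "month_cat:JuneJuly"} <= terms


class TestOddsRatios:
    def test_table_is_exp_of_coefficients(self, cleaned_frame):
        from heifersim.model import LR_SPEC

        X, y, names, levels = build_design_matrix(cleaned_frame, LR_SPEC)
        fit = fit_logistic(X, y, names=names, spec=LR_SPEC, levels=levels)
        table = odds_ratio_table(fit).set_index("term")
        for name, coef in zip(fit.names, fit.coef):
            if name == "(Intercept)":
                continue
            assert table.loc[name, "odds_ratio"] == pytest.approx(np.exp(coef), rel=1e-12)

    def test_reference_levels_have_unit_odds_and_no_interval(self, cleaned_frame):
        from heifersim.model import LR_SPEC

        X, y, names, levels = build_design_matrix(cleaned_frame, LR_SPEC)
        fit = fit_logistic(X, y, names=names, spec=LR_SPEC, levels=levels)
        table = odds_ratio_table(fit).set_index("term")
        row = table.loc["breed:FR (ref)"]
        assert row["odds_ratio"] == 1.0 and pd.isna(row["ci_low"])

    def test_interacting_main_effects_carry_no_p_value(self, cleaned_frame):
        from heifersim.model import LR_SPEC

        X, y, names, levels = build_design_matrix(cleaned_frame, LR_SPEC)
        fit = fit_logistic(X, y, names=names, spec=LR_SPEC, levels=levels)
        table = odds_ratio_table(fit).set_index("term")
        assert pd.isna(table.loc["age10", "p_value"])
        assert pd.isna(table.loc["month_cat:May", "p_value"])
        assert not pd.isna(table.loc["civ_pta", "p_value"])

    def test_ci_uses_requested_confidence(self, cleaned_frame):
        spec = ModelSpec(continuous_terms=("civ_pta",))
        X, y, names, _ = build_design_matrix(cleaned_frame, spec)
        fit = fit_logistic(X, y, names=names, spec=spec)
        t95 = odds_ratio_table(fit, 0.95).set_index("term")
        j = fit.names.index("civ_pta")
        z = norm.ppf(0.975)
        assert t95.loc["civ_pta", "ci_low"] == pytest.approx(
            np.exp(fit.coef[j] - z * fit.se[j])
        )
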