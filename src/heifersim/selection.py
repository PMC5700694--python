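"""Stepwise term selection, the log-interaction linearity check,
variable-importance ranking and odds-ratio tables.

Selection follows the study's protocol: a univariate likelihood-ratio
screen at P <= 0.2, backward elimination of terms with P > 0.2, forward
addition of remaining candidates (including two-way interactions of
included terms) at P <= 0.05, alternated until a full pass changes
nothing.  Factor terms are tested as blocks (multi-df likelihood-ratio
tests); hierarchy is respected — a main effect is never dropped while an
interaction involving it is in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .errors import DomainError
from .logistic import fit_logistic
from .model import ModelFit, ModelSpec, build_design_matrix, infer_levels


def _fit_spec(df, spec: ModelSpec, levels) -> ModelFit:
    X, y, names, _ = build_design_matrix(df, spec, levels)
    return fit_logistic(X, y, names=names, spec=spec, levels=levels)


def lr_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df_diff = len(full.names) - len(reduced.names)
    return stat, df_diff, float(chi2.sf(stat, df_diff)) if df_diff > 0 else np.nan


def _spec_without(spec: ModelSpec, term) -> ModelSpec:
    if isinstance(term, tuple):
        return spec.with_terms(
            interaction_terms=tuple(t for t in spec.interaction_terms if t != term)
        )
    return spec.with_terms(
        factor_terms=tuple(t for t in spec.factor_terms if t != term),
        continuous_terms=tuple(t for t in spec.continuous_terms if t != term),
        interaction_terms=tuple(
            t for t in spec.interaction_terms if term not in t
        ),
    )


def _spec_with(spec: ModelSpec, term, kind: str) -> ModelSpec:
    if kind == "interaction":
        return spec.with_terms(interaction_terms=spec.interaction_terms + (term,))
    if kind == "factor":
        return spec.with_terms(factor_terms=spec.factor_terms + (term,))
    return spec.with_terms(continuous_terms=spec.continuous_terms + (term,))


def univariate_screen(df, candidates: dict, levels, alpha: float = 0.2) -> dict:
    """Single-term likelihood-ratio P-values against the intercept-only model."""
    null = _fit_spec(df, ModelSpec(), levels)
    pvals = {}
    for term in sorted(candidates):
        spec = _spec_with(ModelSpec(), term, candidates[term])
        _, _, p = lr_test(_fit_spec(df, spec, levels), null)
        pvals[term] = p
    return {t: p for t, p in pvals.items() if p <= alpha}, pvals


def stepwise_select(
    df: pd.DataFrame,
    candidates: dict,
    alpha_screen: float = 0.2,
    alpha_stay: float = 0.2,
    alpha_enter: float = 0.05,
    max_rounds: int = 50,
) -> ModelSpec:
    """Stepwise construction of a fixed-effects logistic model.

    ``candidates`` maps term name -> "factor" | "continuous".  Candidate
    terms are scanned in alphabetical order for determinism.  Returns at
    minimum the intercept-only spec.
    """
    levels = infer_levels(df, ModelSpec(factor_terms=tuple(
        t for t, k in candidates.items() if k == "factor"
    )))
    screened, _ = univariate_screen(df, candidates, levels, alpha_screen)
    spec = ModelSpec(
        factor_terms=tuple(sorted(t for t in screened if candidates[t] == "factor")),
        continuous_terms=tuple(sorted(t for t in screened if candidates[t] == "continuous")),
    )
    for _ in range(max_rounds):
        changed = False
        # backward: drop the least significant droppable term with P > alpha_stay
        while True:
            fit = _fit_spec(df, spec, levels)
            droppable = list(spec.interaction_terms) + [
                t
                for t in list(spec.factor_terms) + list(spec.continuous_terms)
                if not any(t in it for it in spec.interaction_terms)
            ]
            worst, worst_p = None, alpha_stay
            for term in sorted(droppable, key=str):
                _, _, p = lr_test(fit, _fit_spec(df, _spec_without(spec, term), levels))
                if p > worst_p:
                    worst, worst_p = term, p
            if worst is None:
                break
            spec = _spec_without(spec, worst)
            changed = True
        # forward: add the most significant candidate with P <= alpha_enter
        fit = _fit_spec(df, spec, levels)
        included = set(spec.factor_terms) | set(spec.continuous_terms)
        pool = [
            (t, candidates[t]) for t in sorted(candidates) if t not in included
        ] + [
            ((a, b), "interaction")
            for a, b in _pairs(sorted(included))
            if (a, b) not in spec.interaction_terms
        ]
        best, best_p, best_kind = None, alpha_enter, None
        for term, kind in pool:
            try:
                cand_fit = _fit_spec(df, _spec_with(spec, term, kind), levels)
            except Exception:
                continue
            _, _, p = lr_test(cand_fit, fit)
            if (best is None and p <= alpha_enter) or (best is not None and p < best_p):
                best, best_p, best_kind = term, p, kind
        if best is not None:
            spec = _spec_with(spec, best, best_kind)
            changed = True
        if not changed:
            break
    return spec


def _pairs(items):
    items = list(items)
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            yield (a, b)


def linearity_check(df: pd.DataFrame, continuous_terms, scale: dict | None = None) -> dict:
    """Wald P-values for x * ln(x) terms; P >= 0.05 leaves linearity standing.

    Each term must be strictly positive after the documented rescaling
    (``scale`` maps term -> divisor; age in days is positive and is
    rescaled to units of its divisor so ln(x) stays near zero).
    """
    scale = scale or {}
    cols, names = [np.ones(len(df))], ["(Intercept)"]
    log_cols = []
    for term in continuous_terms:
        x = df[term].to_numpy(dtype=float) / float(scale.get(term, 1.0))
        if np.unique(x).size < 2:
            raise DomainError(f"continuous term {term!r} is constant")
        if np.any(x <= 0):
            raise DomainError(f"term {term!r} not strictly positive after rescaling")
        cols.append(x)
        names.append(term)
        cols.append(x * np.log(x))
        names.append(f"{term}:log")
        log_cols.append(f"{term}:log")
    X = np.column_stack(cols)
    y = (df["outcome"] == "positive").to_numpy(dtype=float)
    # x and x*ln(x) are nearly collinear, so finite coefficients can be
    # large; the separation bound is disabled for this diagnostic fit
    fit = fit_logistic(X, y, names=names, separation_bound=None)
    z = fit.coef / fit.se
    return {
        t: float(2 * norm.sf(abs(z[names.index(t)]))) for t in log_cols
    }


def rank_variable_importance(fit: ModelFit, by: str | None = None) -> pd.DataFrame:
    """Per-coefficient importance ranking.

    For the fixed-effects and additive models coefficients are ranked by
    |z| = |coef/SE| descending (factor levels separately); for the mixed
    model entries are ranked by P-value ascending.  Smooth terms of the
    additive model contribute one entry each, scored by their largest
    basis-coefficient |z|.
    """
    if by is None:
        by = "p" if fit.family == "MLR" else "z"
    se = fit.se
    rows = []
    seen_smooth = set()
    for j, name in enumerate(fit.names):
        if name == "(Intercept)":
            continue
        if name.startswith("s(") and fit.family == "GAM":
            term = name[: name.rindex(")") + 1]
            if term in seen_smooth:
                continue
            idx = [k for k, n in enumerate(fit.names) if n.startswith(term)]
            z = float(np.max(np.abs(fit.coef[idx] / se[idx])))
            rows.append((term, z))
            seen_smooth.add(term)
        else:
            rows.append((name, float(abs(fit.coef[j] / se[j]))))
    out = pd.DataFrame(rows, columns=["term", "abs_z"])
    out["p_value"] = 2 * norm.sf(out["abs_z"])
    key = "abs_z" if by == "z" else "p_value"
    out = out.sort_values(key, ascending=(by != "z"), kind="stable").reset_index(drop=True)
    out.index = out.index + 1
    out.index.name = "rank"
    return out


@dataclass
class OddsRatioRow:
    term: str
    odds_ratio: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None


def odds_ratio_table(fit: ModelFit, confidence: float = 0.95) -> pd.DataFrame:
    """exp(coefficients) with Wald confidence intervals.

    Reference levels are reported as OR 1 with no interval; main effects
    involved in an interaction carry no P-value, following the convention
    of the study's odds-ratio table.
    """
    z = norm.ppf(0.5 + confidence / 2.0)
    se = fit.se
    interacting = set()
    if fit.spec is not None:
        for a, b in fit.spec.interaction_terms:
            interacting.update((a, b))
    rows = []
    if fit.levels:
        ref_done = set()
        for term, lv in fit.levels.items():
            rows.append(OddsRatioRow(f"{term}:{lv[0]} (ref)", 1.0, None, None, None))
            ref_done.add(term)
    for j, name in enumerate(fit.names):
        if name == "(Intercept)":
            continue
        term_base = name.split(":")[0]
        in_interaction = "*" not in name and (
            term_base in interacting or name in interacting
        )
        p = None if in_interaction else float(2 * norm.sf(abs(fit.coef[j] / se[j])))
        rows.append(
            OddsRatioRow(
                name,
                float(np.exp(fit.coef[j])),
                float(np.exp(fit.coef[j] - z * se[j])),
                float(np.exp(fit.coef[j] + z * se[j])),
                p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
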