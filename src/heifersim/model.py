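"""Model specification, design-matrix construction and shared fit container.

Factors use treatment (dummy) coding against a stated reference level:
breed against FR (Friesian), month against April, year against its
earliest level.  Continuous age enters as ``(age_days - center)/10``; the
centring constant is a numerical-conditioning choice only and predictions
are invariant to it.  Interaction columns are elementwise products of the
columns of the two interacting terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

#: Default age centring (days); near the herd mean ages, conditioning only.
AGE_CENTER_DAYS = 460.0


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter a model and how."""

    factor_terms: tuple = ()
    continuous_terms: tuple = ()
    interaction_terms: tuple = ()  # pairs of term names
    smooth_terms: tuple = ()  # additive model only
    random_intercept: Optional[str] = None  # e.g. "herd:year"

    def __post_init__(self):
        overlap = set(self.continuous_terms) & set(self.smooth_terms)
        if overlap:
            raise DomainError(f"terms in both continuous and smooth: {sorted(overlap)}")
        included = set(self.factor_terms) | set(self.continuous_terms) | set(self.smooth_terms)
        for a, b in self.interaction_terms:
            if a not in included or b not in included:
                raise DomainError(f"interaction ({a}, {b}) involves an excluded term")

    def with_terms(self, **kwargs) -> "ModelSpec":
        cur = dict(
            factor_terms=self.factor_terms,
            continuous_terms=self.continuous_terms,
            interaction_terms=self.interaction_terms,
            smooth_terms=self.smooth_terms,
            random_intercept=self.random_intercept,
        )
        cur.update(kwargs)
        return ModelSpec(**cur)

    @property
    def terms(self) -> tuple:
        return tuple(self.factor_terms) + tuple(self.continuous_terms) + tuple(
            self.smooth_terms
        ) + tuple(self.interaction_terms)


@dataclass
class ModelFit:
    """Fitted coefficients and inference state for any model family."""

    family: str  # "LR", "MLR" or "GAM"
    names: list
    coef: np.ndarray
    cov: Optional[np.ndarray]
    loglik: float
    converged: bool
    n_iter: int
    random_effect_sd: Optional[float] = None
    spec: Optional[ModelSpec] = None
    levels: Optional[dict] = None
    extras: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def infer_levels(df: pd.DataFrame, spec: ModelSpec) -> dict:
    """Reference-first level lists for every factor in the spec."""
    preferred = {"breed": "FR", "month_cat": "April"}
    levels = {}
    for term in spec.factor_terms:
        obs = sorted(df[term].dropna().unique().tolist())
        ref = preferred.get(term, obs[0] if obs else None)
        if ref in obs:
            obs.remove(ref)
            obs = [ref] + obs
        levels[term] = tuple(obs)
    return levels


def _encode_term(df: pd.DataFrame, term: str, levels: dict):
    """Columns and names for one (non-smooth) term."""
    if term in levels:  # factor
        lv = levels[term]
        vals = df[term].to_numpy()
        unseen = set(pd.unique(vals)) - set(lv)
        if unseen:
            raise DomainError(f"unseen level(s) {sorted(map(str, unseen))} for factor {term!r}")
        cols = [(vals == l).astype(float) for l in lv[1:]]
        names = [f"{term}:{l}" for l in lv[1:]]
        return cols, names
    x = pd.to_numeric(df[term]).to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DomainError(f"missing values in continuous term {term!r}")
    return [x], [term]


def build_design_matrix(
    df: pd.DataFrame,
    spec: ModelSpec,
    levels: Optional[dict] = None,
    outcome_col: str = "outcome",
):
    """Construct (X, y, names, levels) for the fixed-effects part of a spec.

    ``y`` is None when ``outcome_col`` is absent (prediction time).
    Passing the ``levels`` returned at training time guarantees an
    identical column layout; an unseen factor level raises, naming it.
    """
    if levels is None:
        levels = infer_levels(df, spec)
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    encoded = {}
    for term in list(spec.factor_terms) + list(spec.continuous_terms):
        c, nm = _encode_term(df, term, levels)
        encoded[term] = (c, nm)
        cols.extend(c)
        names.extend(nm)
    for a, b in spec.interaction_terms:
        ca, na = encoded.get(a) or _encode_term(df, a, levels)
        cb, nb = encoded.get(b) or _encode_term(df, b, levels)
        for xa, nma in zip(ca, na):
            for xb, nmb in zip(cb, nb):
                cols.append(xa * xb)
                names.append(f"{nma}*{nmb}")
    X = np.column_stack(cols)
    y = None
    if outcome_col in df.columns:
        o = df[outcome_col]
        if o.isin(["positive", "negative"]).all():
            y = (o == "positive").to_numpy(dtype=float)
        else:
            y = pd.to_numeric(o).to_numpy(dtype=float)
    return X, y, names, levels


def model_frame(
    cleaned: pd.DataFrame,
    age_center_days: float = AGE_CENTER_DAYS,
    year_pool_from: Optional[int] = 2013,
) -> pd.DataFrame:
    """Modelling frame from cleaned records: complete cases, derived terms.

    Records missing breed or CIV PTA are dropped here (not during
    cleaning).  ``age10`` is centred age in 10-day units; ``year_cat``
    pools years >= ``year_pool_from``.
    """
    df = cleaned.copy()
    complete = df["breed"].notna() & df["civ_pta"].notna()
    df = df[complete].copy()
    df["age10"] = (df["age_days"].astype(float) - age_center_days) / 10.0
    years = pd.to_datetime(df["service_date"]).dt.year
    if year_pool_from is not None:
        df["year_cat"] = np.where(
            years >= year_pool_from, f">={year_pool_from}", years.astype(str)
        )
    else:
        df["year_cat"] = years.astype(str)
    df["herd_year"] = df["herd_id"].astype(str) + ":" + years.astype(str)
    return df.reset_index(drop=True)


#: The final fixed-effects structure of the study's regression models.
LR_SPEC = ModelSpec(
    factor_terms=("breed", "month_cat", "year_cat"),
    continuous_terms=("age10", "civ_pta"),
    interaction_terms=(("age10", "month_cat"),),
)
MLR_SPEC = ModelSpec(
    factor_terms=("breed", "month_cat"),
    continuous_terms=("age10", "civ_pta"),
    interaction_terms=(("age10", "month_cat"),),
    random_intercept="herd_year",
)
GAM_SPEC = ModelSpec(
    factor_terms=("breed", "month_cat", "year_cat"),
    smooth_terms=("age10", "civ_pta"),
)


def predict_probabilities(fit: ModelFit, records: pd.DataFrame) -> np.ndarray:
    """Conception probabilities for new records under a fitted model.

    Mixed-model predictions set the random intercept to zero (its mean),
    i.e. they are the fixed-effects-only probabilities.
    """
    if fit.family == "GAM":
        from .gam import predict_gam

        return predict_gam(fit, records)
    X, _, names, _ = build_design_matrix(records, fit.spec, fit.levels, outcome_col="__none__")
    if names != list(fit.names):
        raise DomainError("prediction design does not match the fitted model")
    eta = X @ fit.coef
    from scipy.special import expit

    return expit(eta)
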