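"""The generative conception model: published odds ratios, intercept
calibration and Bernoulli outcome simulation.

The packaged parameter set applies the study's mixed-model odds ratios
on the logit scale:

    logit P(conception) = c + b_breed + b_age * age10 + b_civ * civ
                          + b_month + g_month * age10 + u(herd-year)

with age10 = (age_days - age_center_days)/10 and u ~ N(0, sd^2).  The
published table prints no intercept, so ``calibrate_intercept`` finds by
bisection the value that reproduces a target marginal conception rate
over a sampled covariate and random-effect distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ConfigError, DomainError


@dataclass(frozen=True)
class GenerativeParams:
    """Logit-scale coefficients of the conception model."""

    intercept: float | None
    breed_log_or: dict = field(default_factory=dict)  # vs FR
    age_log_or_per_10d: float = 0.0
    civ_log_or_per_day: float = 0.0
    month_log_or: dict = field(default_factory=dict)  # vs April
    age_month_log_or: dict = field(default_factory=dict)
    random_effect_sd: float = 0.0
    age_center_days: float = 0.0
    target_conception_rate: float = 0.777

    def with_intercept(self, intercept: float) -> "GenerativeParams":
        return replace(self, intercept=float(intercept))


def published_params() -> GenerativeParams:
    """The packaged published parameter set (intercept uncalibrated)."""
    text = resources.files("heifersim").joinpath("params/published_odds_ratios.yaml").read_text()
    raw = yaml.safe_load(text)
    ors = raw["odds_ratios"]
    for group in ("breed", "month", "age_x_month"):
        for k, v in ors[group].items():
            if v <= 0:
                raise ConfigError(f"odds ratio for {group}:{k} must be positive")
    return GenerativeParams(
        intercept=raw["intercept"],
        breed_log_or={k: float(np.log(v)) for k, v in ors["breed"].items()},
        age_log_or_per_10d=float(np.log(ors["age_per_10d"])),
        civ_log_or_per_day=float(np.log(ors["civ_per_day"])),
        month_log_or={k: float(np.log(v)) for k, v in ors["month"].items()},
        age_month_log_or={k: float(np.log(v)) for k, v in ors["age_x_month"].items()},
        random_effect_sd=float(raw["random_effect_sd"]),
        age_center_days=float(raw["age_center_days"]),
        target_conception_rate=float(raw["target_conception_rate"]),
    )


def linear_predictor(records: pd.DataFrame, params: GenerativeParams, include_intercept=True):
    """Fixed-effects logit for each record (random intercepts excluded)."""
    age10 = (records["age_days"].to_numpy(dtype=float) - params.age_center_days) / 10.0
    eta = params.age_log_or_per_10d * age10
    eta = eta + params.civ_log_or_per_day * records["civ_pta"].to_numpy(dtype=float)
    breed = records["breed"].to_numpy()
    month = records["month_cat"].to_numpy()
    eta = eta + np.array([params.breed_log_or.get(b, 0.0) for b in breed])
    eta = eta + np.array([params.month_log_or.get(m, 0.0) for m in month])
    eta = eta + np.array([params.age_month_log_or.get(m, 0.0) for m in month]) * age10
    if include_intercept:
        if params.intercept is None:
            raise ConfigError("intercept not calibrated; call calibrate_intercept first")
        eta = eta + params.intercept
    return eta


def simulate_outcomes(probabilities, seed=None, rng=None) -> np.ndarray:
    """Independent Bernoulli draws; deterministic given the seed."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("probabilities must lie strictly in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    return (rng.random(p.shape) < p).astype(int)


def calibrate_intercept(
    params: GenerativeParams,
    covariate_sampler,
    target_rate: float | None = None,
    seed: int = 0,
    n_sample: int = 100_000,
    tol: float = 0.005,
) -> float:
    """Logit intercept matching a target marginal conception rate.

    ``covariate_sampler(n, rng)`` must return a frame with ``age_days``,
    ``civ_pta``, ``breed`` and ``month_cat``.  The marginal rate is the
    Monte-Carlo average of expit(intercept + eta + u) with u drawn from
    the random-intercept distribution, and the intercept solves
    rate(intercept) = target by bisection (the rate is strictly
    increasing in the intercept).
    """
    if target_rate is None:
        target_rate = params.target_conception_rate
    if not 0.0 < target_rate < 1.0:
        raise DomainError("target rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cov = covariate_sampler(n_sample, rng)
    eta0 = linear_predictor(cov, params, include_intercept=False)
    eta0 = eta0 + rng.normal(0.0, params.random_effect_sd, size=len(cov))

    def rate(c):
        return float(np.mean(expit(eta0 + c))) - target_rate

    lo, hi = -30.0, 30.0
    if rate(lo) > 0 or rate(hi) < 0:
        raise ConfigError("failed to bracket the intercept: check covariate sampler")
    c = brentq(rate, lo, hi, xtol=1e-6)
    achieved = rate(c) + target_rate
    if abs(achieved - target_rate) > tol:
        raise ConfigError(f"calibration missed target: {achieved:.4f} vs {target_rate:.4f}")
    return float(c)
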