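"""Reproduction experiments: the headline quantities recomputed from scratch.

Each function runs one seeded replicate of a self-contained simulation
experiment built on the packaged published parameter set:

* held-out mean absolute calibration error of a correctly specified
  mixed-model fit on a ~30% test split of a study-sized synthetic herd;
* recovery of the per-day calving-interval-PTA odds ratio from a large
  single-level logistic simulation;
* recovery of the herd-year random-intercept SD from a grouped
  mixed-model simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cleaning import clean_pipeline
from .evaluation import binned_residuals_mace
from .logistic import fit_logistic
from .mixed import fit_mixed_logistic
from .model import MLR_SPEC, build_design_matrix, model_frame, predict_probabilities
from .partition import stratified_split
from .synthetic import (
    SyntheticConfig,
    covariate_sampler_from_config,
    generate_dataset,
    published_params,
)

CIV_OR_TRUE = 0.93
RE_SD_TRUE = 0.78
TARGET_RATE = 0.777


def heldout_mace_replicate(seed: int, proportion: float = 0.7) -> tuple[float, int]:
    """(MACE %, test size) for one simulate/clean/split/fit/predict cycle.

    A study-sized synthetic herd (~2,000 services) is generated from the
    packaged odds-ratio model, cleaned, split 70/30 with outcome
    stratification, and the mixed logistic model is refitted on the
    training records.  Held-out predictions set the random intercepts to
    zero; MACE uses the default floor(sqrt(n)) grouping.
    """
    config = SyntheticConfig(seed=seed)
    services, calvings, _ = generate_dataset(config, with_defects=False)
    cleaned, _ = clean_pipeline(services, calvings)
    frame = model_frame(cleaned)
    y = (frame["outcome"] == "positive").to_numpy(dtype=int)
    split = stratified_split(y, proportion, seed)
    train = frame.iloc[split.train_indices]
    test = frame.iloc[split.test_indices]
    X, yy, names, levels = build_design_matrix(train, MLR_SPEC)
    fit = fit_mixed_logistic(
        X, yy, train["herd_year"], names=names, spec=MLR_SPEC, levels=levels
    )
    p = predict_probabilities(fit, test)
    _, mace = binned_residuals_mace(p, (test["outcome"] == "positive").to_numpy(float))
    return mace, len(test)


def civ_or_replicate(seed: int, n: int = 20_000, civ_sd: float = 1.5) -> float:
    """Recovered exp(CIV coefficient) from a single-level logistic simulation."""
    rng = np.random.default_rng(seed)
    civ = rng.normal(0.0, civ_sd, n)
    b = np.log(CIV_OR_TRUE)
    c = brentq(lambda c0: np.mean(expit(c0 + b * civ)) - TARGET_RATE, -10, 10)
    y = (rng.random(n) < expit(c + b * civ)).astype(float)
    X = np.column_stack([np.ones(n), civ])
    fit = fit_logistic(X, y, names=["(Intercept)", "civ_pta"])
    return float(np.exp(fit.coef[1]))


def re_sd_replicate(seed: int, n_groups: int = 60, group_size: int = 40) -> float:
    """Recovered random-intercept SD from a grouped generative simulation."""
    rng = np.random.default_rng(seed)
    config = SyntheticConfig(seed=seed)
    params = published_params()
    sampler = covariate_sampler_from_config(config)
    n = n_groups * group_size
    frame = sampler(n, rng)
    from .generative import calibrate_intercept, linear_predictor

    params = params.with_intercept(
        calibrate_intercept(params, sampler, seed=int(rng.integers(2**31)))
    )
    groups = np.repeat(np.arange(n_groups), group_size)
    u = rng.normal(0.0, params.random_effect_sd, n_groups)
    eta = linear_predictor(frame, params) + u[groups]
    frame = frame.copy()
    frame["outcome"] = np.where(rng.random(n) < expit(eta), "positive", "negative")
    frame["age10"] = (frame["age_days"] - 460.0) / 10.0
    frame["herd_year"] = pd.Series(groups).map("G{:03d}".format).to_numpy()
    X, y, names, levels = build_design_matrix(frame, MLR_SPEC)
    fit = fit_mixed_logistic(X, y, frame["herd_year"], names=names)
    return float(fit.random_effect_sd)
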