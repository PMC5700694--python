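"""End-to-end orchestration: simulate -> clean -> split -> fit -> evaluate.

A single master seed deterministically spawns one sub-seed per stage
(via ``numpy.random.SeedSequence``), so every number in the final report
bundle is reproducible from the configuration alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cleaning, evaluation, model, partition, synthetic
from .errors import ConfigError
from .gam import fit_gam
from .logistic import fit_logistic
from .mixed import fit_mixed_logistic
from .model import GAM_SPEC, LR_SPEC, MLR_SPEC, build_design_matrix, predict_probabilities

log = logging.getLogger("heifersim")

SCHEMA_VERSION = "heifersim-report-1"
_STAGES = ("simulate", "inject", "split", "fit", "evaluate")


@dataclass(frozen=True)
class PipelineConfig:
    master_seed: int = 0
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    with_defects: bool = True
    cleaning: cleaning.CleaningConfig = field(default_factory=cleaning.CleaningConfig)
    split_proportion: float = 0.7
    n_bootstrap: int = 2000
    families: tuple = ("LR", "MLR", "GAM")
    thresholds: tuple = (0.5, "optimal")

    def __post_init__(self):
        if not 0.0 < self.split_proportion < 1.0:
            raise ConfigError("split proportion must lie in (0, 1)")
        unknown = set(self.families) - {"LR", "MLR", "GAM"}
        if unknown:
            raise ConfigError(f"unknown model families: {sorted(unknown)}")

    def stage_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.master_seed)
        states = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(_STAGES))]
        return dict(zip(_STAGES, states))


def fit_family(family: str, train: pd.DataFrame):
    """Fit one of the three model families on a modelling frame."""
    if family == "LR":
        X, y, names, levels = build_design_matrix(train, LR_SPEC)
        return fit_logistic(X, y, names=names, spec=LR_SPEC, levels=levels)
    if family == "MLR":
        X, y, names, levels = build_design_matrix(train, MLR_SPEC)
        return fit_mixed_logistic(
            X, y, train["herd_year"], names=names, spec=MLR_SPEC, levels=levels
        )
    if family == "GAM":
        return fit_gam(train, GAM_SPEC)
    raise ConfigError(f"unknown family {family!r}")


def evaluate_fit(fit, test: pd.DataFrame, thresholds=(0.5, "optimal")) -> dict:
    """Discrimination (per threshold) and calibration reports on held-out data."""
    p = predict_probabilities(fit, test)
    y = (test["outcome"] == "positive").to_numpy(dtype=float)
    out = {"n_test": int(len(test)), "discrimination": {}}
    for t in thresholds:
        t_val = evaluation.optimal_threshold(p, y) if t == "optimal" else float(t)
        rep = evaluation.discrimination_report(p, y, t_val)
        out["discrimination"]["optimal" if t == "optimal" else f"{t_val:g}"] = rep.as_dict()
    out["calibration"] = evaluation.calibration_report(p, y).as_dict()
    return out


def run_end_to_end(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the versioned report bundle."""
    seeds = config.stage_seeds()
    bundle = {"schema": SCHEMA_VERSION, "master_seed": config.master_seed, "stages": {}}
    t0 = time.perf_counter()

    scfg = replace(config.synthetic, seed=seeds["simulate"])
    services, calvings, ledger = synthetic.generate_dataset(
        scfg, with_defects=config.with_defects
    )
    log.info("simulated %d services, %d calvings", len(services), len(calvings))
    bundle["stages"]["simulate"] = {
        "n_services": int(len(services)),
        "n_calvings": int(len(calvings)),
        "planted_defects": ledger.counts(),
    }

    cleaned, audit = cleaning.clean_pipeline(services, calvings, config.cleaning)
    log.info("cleaned: %d -> %d records", audit.n_input, audit.n_output)
    bundle["stages"]["clean"] = {"audit": audit.as_dict()}

    frame = model.model_frame(cleaned)
    y = (frame["outcome"] == "positive").to_numpy(dtype=int)
    split = partition.stratified_split(y, config.split_proportion, seeds["split"])
    train = frame.iloc[split.train_indices].reset_index(drop=True)
    test = frame.iloc[split.test_indices].reset_index(drop=True)
    log.info(
        "modelling frame %d complete records; split %d train / %d test",
        len(frame),
        len(train),
        len(test),
    )
    bundle["stages"]["split"] = {
        "n_complete": int(len(frame)),
        "n_dropped_incomplete": int(len(cleaned) - len(frame)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "train_conception_rate": float(y[split.train_indices].mean()),
        "test_conception_rate": float(y[split.test_indices].mean()),
    }

    bundle["stages"]["fit"] = {}
    bundle["stages"]["evaluate"] = {}
    for family in config.families:
        t_fit = time.perf_counter()
        fit = fit_family(family, train)
        log.info("fitted %s in %.2fs (loglik %.2f)", family, time.perf_counter() - t_fit, fit.loglik)
        entry = {
            "coefficients": dict(zip(fit.names, fit.coef.tolist())),
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_iterations": fit.n_iter,
        }
        if fit.random_effect_sd is not None:
            entry["random_effect_sd"] = fit.random_effect_sd
        if fit.family == "GAM":
            entry["edf_terms"] = fit.extras["edf_terms"]
            entry["lambdas"] = fit.extras["lambdas"]
        bundle["stages"]["fit"][family] = entry
        bundle["stages"]["evaluate"][family] = evaluate_fit(fit, test, config.thresholds)

    bundle["elapsed_seconds"] = time.perf_counter() - t0
    return bundle


def write_bundle(bundle: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
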