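"""Two-pronged predictive evaluation of binary conception models.

*Discrimination* — confusion-matrix metrics at a threshold (predicted
positive iff probability >= threshold), the Matthews correlation
coefficient, the ROC curve swept over observed probabilities, the
trapezoidal AUC (with ties handled so it equals the probability a random
positive outscores a random negative, counting ties half) and the
Youden-J optimal threshold.

*Calibration* — the Hosmer-Lemeshow chi-square over deciles of risk,
equal-width calibration bins with exact (Clopper-Pearson) binomial
intervals, the unreliability likelihood-ratio test of the calibration
line against intercept 0 / slope 1, and binned residuals summarized by
the mean absolute calibration error (MACE, in percent).

Degenerate cells follow the printed conventions of the study: any 0/0
metric and a zero-denominator MCC are reported as 0, matching the
all-positive classifier column of its discrimination table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .errors import DomainError
from .logistic import bernoulli_loglik, irls


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiscriminationReport:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    mcc: float
    auc: float
    roc_points: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["roc_points"] = None if self.roc_points is None else self.roc_points.tolist()
        return d


@dataclass
class CalibrationReport:
    hl_statistic: float
    hl_df: int
    hl_p: float
    bins: pd.DataFrame = field(repr=False, default=None)
    unreliability_statistic: float = np.nan
    unreliability_p: float = np.nan
    binned_residuals: np.ndarray = field(repr=False, default=None)
    mace: float = np.nan

    def as_dict(self) -> dict:
        return {
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "bins": None
            if self.bins is None
            else self.bins.astype(object).where(pd.notna(self.bins), None).to_dict(orient="list"),
            "unreliability_statistic": self.unreliability_statistic,
            "unreliability_p": self.unreliability_p,
            "binned_residuals": None
            if self.binned_residuals is None
            else np.asarray(self.binned_residuals).tolist(),
            "mace": self.mace,
        }


def _check_inputs(probabilities, outcomes):
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.size == 0:
        raise DomainError("empty input")
    if p.shape != y.shape:
        raise DomainError("probabilities and outcomes differ in length")
    return p, y


def confusion_matrix(probabilities, outcomes, threshold: float = 0.5) -> ConfusionMatrix:
    p, y = _check_inputs(probabilities, outcomes)
    pred = p >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num, den) -> float:
    return num / den if den else 0.0


def discrimination_metrics(m: ConfusionMatrix, threshold: float = 0.5) -> DiscriminationReport:
    """Percent-scale confusion metrics plus the MCC."""
    denom = (
        (m.tp + m.fp) * (m.tp + m.fn) * (m.tn + m.fp) * (m.tn + m.fn)
    )
    mcc = ((m.tp * m.tn - m.fp * m.fn) / math.sqrt(denom)) if denom else 0.0
    return DiscriminationReport(
        threshold=threshold,
        sensitivity=100.0 * _ratio(m.tp, m.tp + m.fn),
        specificity=100.0 * _ratio(m.tn, m.tn + m.fp),
        ppv=100.0 * _ratio(m.tp, m.tp + m.fp),
        npv=100.0 * _ratio(m.tn, m.tn + m.fn),
        accuracy=100.0 * _ratio(m.tp + m.tn, m.n),
        mcc=float(mcc),
        auc=np.nan,
    )


def roc_and_auc(probabilities, outcomes):
    """ROC sweep over unique probabilities and the trapezoidal AUC."""
    p, y = _check_inputs(probabilities, outcomes)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both outcome classes are required for a ROC curve")
    order = np.argsort(-p, kind="stable")
    ps, ys = p[order], y[order]
    # group ties so each unique probability contributes one ROC point
    _, starts = np.unique(-ps, return_index=True)
    ends = np.append(starts[1:], ps.size)
    tp = np.cumsum(ys)[ends - 1]
    fp = np.cumsum(1 - ys)[ends - 1]
    tpr = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def optimal_threshold(probabilities, outcomes) -> float:
    """The observed probability maximizing Youden's J; ties -> smallest."""
    p, y = _check_inputs(probabilities, outcomes)
    n_pos = np.sum(y == 1)
    n_neg = np.sum(y == 0)
    best_t, best_j = None, -np.inf
    for t in np.unique(p):
        pred = p >= t
        j = np.sum(pred & (y == 1)) / n_pos + np.sum(~pred & (y == 0)) / n_neg - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t


def discrimination_report(probabilities, outcomes, threshold: float = 0.5) -> DiscriminationReport:
    report = discrimination_metrics(confusion_matrix(probabilities, outcomes, threshold), threshold)
    report.roc_points, report.auc = roc_and_auc(probabilities, outcomes)
    return report


def hosmer_lemeshow(probabilities, outcomes, n_groups: int = 10):
    """Hosmer-Lemeshow chi-square over equal-sized groups of sorted risk."""
    p, y = _check_inputs(probabilities, outcomes)
    if p.size < 2 * n_groups:
        raise DomainError(f"need at least {2 * n_groups} records for {n_groups} groups")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    obs1 = np.array([y[g].sum() for g in groups])
    exp1 = np.array([p[g].sum() for g in groups])
    sizes = np.array([g.size for g in groups], dtype=float)
    # merge any group with a zero expected cell into its neighbour
    while np.any((exp1 <= 0) | (exp1 >= sizes)) and obs1.size > 2:
        i = int(np.argmax((exp1 <= 0) | (exp1 >= sizes)))
        j = i - 1 if i > 0 else i + 1
        warnings.warn("merging Hosmer-Lemeshow group with empty expected cell", stacklevel=2)
        keep = [k for k in range(obs1.size) if k != i]
        obs1[j] += obs1[i]
        exp1[j] += exp1[i]
        sizes[j] += sizes[i]
        obs1, exp1, sizes = obs1[keep], exp1[keep], sizes[keep]
    obs0, exp0 = sizes - obs1, sizes - exp1
    stat = float(np.sum((obs1 - exp1) ** 2 / exp1) + np.sum((obs0 - exp0) ** 2 / exp0))
    df = int(obs1.size - 2)
    return stat, df, float(chi2.sf(stat, df))


def exact_binomial_ci(k: int, m: int, confidence: float = 0.95):
    """Clopper-Pearson interval (the F/beta-quantile exact form)."""
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, m - k + 1))
    hi = 1.0 if k == m else float(beta_dist.ppf(1 - alpha / 2, k + 1, m - k))
    return lo, hi


def calibration_bins(
    probabilities,
    outcomes,
    n_bins: int = 15,
    min_plot_size: int = 10,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Equal-width calibration bins with exact binomial intervals.

    Bins with fewer than ``min_plot_size`` records are emitted but
    flagged ``plotted=False``, mirroring the study's plotting rule.
    """
    p, y = _check_inputs(probabilities, outcomes)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        m = int(mask.sum())
        k = int(y[mask].sum())
        lo, hi = exact_binomial_ci(k, m, confidence) if m else (np.nan, np.nan)
        rows.append(
            {
                "bin": b,
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": m,
                "mean_predicted": float(p[mask].mean()) if m else np.nan,
                "observed_proportion": k / m if m else np.nan,
                "ci_low": lo,
                "ci_high": hi,
                "plotted": m >= min_plot_size,
            }
        )
    return pd.DataFrame(rows)


def unreliability_test(probabilities, outcomes):
    """Likelihood-ratio test of the calibration line vs intercept 0, slope 1.

    Refits the outcomes on logit(probability); the statistic compares the
    refitted line with the identity line on 2 degrees of freedom.
    """
    p, y = _check_inputs(probabilities, outcomes)
    if np.any((p <= 0) | (p >= 1)):
        raise DomainError("probabilities must lie strictly in (0, 1)")
    l = logit(p)
    if np.unique(l).size < 2:
        raise DomainError("constant probabilities: calibration line undefined")
    X = np.column_stack([np.ones_like(l), l])
    _, _, ll1, _, _ = irls(X, y)
    ll0 = bernoulli_loglik(y, l)
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return stat, float(chi2.sf(stat, 2))


def binned_residuals_mace(probabilities, outcomes, n_groups: int | None = None):
    """Per-group mean (outcome - probability) and the MACE in percent.

    Groups are equal-sized, formed by a stable sort on the predicted
    probability; the default group count is floor(sqrt(n)).
    """
    p, y = _check_inputs(probabilities, outcomes)
    if n_groups is None:
        n_groups = int(np.floor(np.sqrt(p.size)))
    if not 1 <= n_groups <= p.size:
        raise DomainError("n_groups must lie in [1, n]")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    devs = np.array([float(np.mean(y[g] - p[g])) for g in groups])
    mace = float(np.mean(np.abs(devs)) * 100.0)
    return devs, mace


def calibration_report(probabilities, outcomes, n_bins: int = 15) -> CalibrationReport:
    stat, df, pval = hosmer_lemeshow(probabilities, outcomes)
    bins = calibration_bins(probabilities, outcomes, n_bins=n_bins)
    u_stat, u_p = unreliability_test(probabilities, outcomes)
    devs, mace = binned_residuals_mace(probabilities, outcomes)
    return CalibrationReport(
        hl_statistic=stat,
        hl_df=df,
        hl_p=pval,
        bins=bins,
        unreliability_statistic=u_stat,
        unreliability_p=u_p,
        binned_residuals=devs,
        mace=mace,
    )
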