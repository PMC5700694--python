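"""Binomial logistic regression fitted by iteratively reweighted least
squares (IRLS), with optional quadratic penalty (used by the additive
model's penalized smooths).

At convergence the score equations X' (y - mu) = 0 hold componentwise to
the stated tolerance and the covariance is the inverse Fisher information.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import qr, solve
from scipy.special import expit

from .errors import ConvergenceError, RankDeficiencyError, SeparationError
from .model import ModelFit

MAX_ITER = 200
SCORE_TOL = 1e-8
LL_TOL = 1e-10
SEPARATION_BOUND = 15.0


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+e^eta) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_rank(X: np.ndarray, names):
    _, R, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    if rank < X.shape[1]:
        bad = [names[j] if names is not None else j for j in piv[rank:]]
        raise RankDeficiencyError(bad)


def irls(
    X: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    names=None,
    max_iter: int = MAX_ITER,
    separation_bound: float | None = SEPARATION_BOUND,
):
    """Core (penalized) IRLS loop.

    Returns (coef, cov, loglik, converged, n_iter) where ``loglik`` is the
    unpenalized binomial log-likelihood and ``cov`` the inverse of the
    (penalized) Fisher information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    if penalty is None:
        _check_rank(X, names)
    P = np.zeros((p, p)) if penalty is None else np.asarray(penalty, dtype=float)

    beta = np.zeros(p)
    eta = X @ beta + offset
    ll = bernoulli_loglik(y, eta) - 0.5 * beta @ P @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        score = X.T @ (y - mu) - P @ beta
        info = (X.T * w) @ X + P
        step = solve(info, score, assume_a="pos")
        # step-halving keeps the penalized log-likelihood monotone
        new_beta, new_ll = beta, ll
        for half in range(30):
            cand = beta + step * (0.5**half)
            cand_eta = X @ cand + offset
            cand_ll = bernoulli_loglik(y, cand_eta) - 0.5 * cand @ P @ cand
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                new_beta, new_ll = cand, cand_ll
                break
        eta = X @ new_beta + offset
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll = new_beta, new_ll
        mu = expit(eta)
        score = X.T @ (y - mu) - P @ beta
        if np.max(np.abs(score)) < SCORE_TOL or rel < LL_TOL:
            converged = True
            break
    # under separation the likelihood has no finite maximizer: coefficients
    # escape while the score vanishes along the divergent path, so the
    # bound itself is the detection rule
    if penalty is None and separation_bound is not None and np.any(
        np.abs(beta) > separation_bound
    ):
        raise SeparationError(
            f"coefficient escaped beyond +/-{separation_bound} on the logit scale; "
            "the data are (quasi-)separated"
        )
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X.T * w) @ X + P
    cov = np.linalg.inv(info)
    return beta, cov, bernoulli_loglik(y, eta), converged, it


def fit_logistic(
    X, y, names=None, offset=None, spec=None, levels=None,
    separation_bound: float | None = SEPARATION_BOUND,
) -> ModelFit:
    """Maximum-likelihood logistic regression via IRLS."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than columns")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    coef, cov, ll, converged, it = irls(
        X, y, offset=offset, names=names, separation_bound=separation_bound
    )
    return ModelFit(
        family="LR",
        names=list(names),
        coef=coef,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=it,
        spec=spec,
        levels=levels,
    )
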