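"""Mixed logistic regression with a single Gaussian random intercept,
fitted by maximizing the marginal likelihood with adaptive Gauss-Hermite
quadrature.

For group g with observations (y_i, x_i) and random intercept
u_g ~ N(0, sigma^2), the marginal contribution is

    L_g = (1 / (sigma sqrt(2 pi))) * Integral exp(h_g(u)) du,
    h_g(u) = sum_i [ y_i eta_i - log(1 + e^{eta_i}) ] - u^2 / (2 sigma^2),
    eta_i = x_i' beta + u.

The quadrature is centred and scaled per group at the mode of h_g
(found by Newton iteration) so few nodes suffice; with a single node the
fit reduces to the Laplace approximation.  Fixed effects and log(sigma)
are optimized jointly with L-BFGS-B; the fixed-effect covariance is the
inverse of a finite-difference Hessian of the negative marginal
log-likelihood at the optimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, roots_hermite
from scipy.special import logsumexp

from .errors import ConvergenceError, DomainError, SeparationError
from .logistic import fit_logistic
from .model import ModelFit

_SIGMA_FLOOR = 1e-4  # below this the variance is reported as a boundary fit


def _group_codes(group_labels):
    codes, uniques = pd.factorize(np.asarray(group_labels), sort=True)
    return codes, len(uniques)


def _find_modes(eta0, y, codes, G, sigma2, u0, n_newton=25):
    """Per-group Newton maximization of h_g(u); fully vectorized over groups."""
    u = u0.copy()
    for _ in range(n_newton):
        eta = eta0 + u[codes]
        mu = expit(eta)
        grad = np.bincount(codes, weights=y - mu, minlength=G) - u / sigma2
        w = np.bincount(codes, weights=mu * (1 - mu), minlength=G)
        hess = -(w + 1.0 / sigma2)
        step = -grad / hess
        # guard against overshoot on flat groups
        step = np.clip(step, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(grad)) < 1e-9:
            break
    eta = eta0 + u[codes]
    mu = expit(eta)
    w = np.bincount(codes, weights=mu * (1 - mu), minlength=G)
    tau = 1.0 / np.sqrt(w + 1.0 / sigma2)
    return u, tau


def marginal_loglik(beta, log_sigma, X, y, codes, G, nodes, weights, u_cache=None):
    """Adaptive Gauss-Hermite marginal log-likelihood."""
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    eta0 = X @ beta
    u0 = np.zeros(G) if u_cache is None else u_cache
    u_hat, tau = _find_modes(eta0, y, codes, G, sigma2, u0)
    K = nodes.size
    # h at the shifted nodes, all groups at once: (G, K)
    u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    h = np.empty((G, K))
    for k in range(K):
        eta = eta0 + u_nodes[codes, k]
        ll_obs = y * eta - np.logaddexp(0.0, eta)
        h[:, k] = np.bincount(codes, weights=ll_obs, minlength=G)
    h -= u_nodes**2 / (2.0 * sigma2)
    log_int = logsumexp(np.log(weights)[None, :] + nodes[None, :] ** 2 + h, axis=1)
    log_int += 0.5 * np.log(2.0) + np.log(tau)
    ll = np.sum(log_int) - G * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi))
    return ll, u_hat


def fit_mixed_logistic(
    X,
    y,
    group_labels,
    n_quadrature_nodes: int = 9,
    names=None,
    spec=None,
    levels=None,
    start=None,
    fix_sigma: float | None = None,
) -> ModelFit:
    """Fit the random-intercept logistic model.

    A variance estimate at (numerical) zero is reported as a boundary fit
    via ``extras["boundary"]`` rather than an error.  ``fix_sigma`` holds
    the random-effect SD fixed (0 reduces the model to plain logistic
    regression) and optimizes the fixed effects only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, G = _group_codes(group_labels)
    if G < 2:
        raise DomainError("need at least two groups for a random intercept")
    if n_quadrature_nodes < 1:
        raise DomainError("need at least one quadrature node")
    nodes, weights = roots_hermite(n_quadrature_nodes)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]

    fixed_log_sigma = None
    if fix_sigma is not None:
        if fix_sigma < 0:
            raise DomainError("fix_sigma must be nonnegative")
        fixed_log_sigma = np.log(max(fix_sigma, 1e-8))
    if start is None:
        try:
            beta0 = fit_logistic(X, y, names=names).coef
        except SeparationError:
            # a separated fixed-effect cell only flattens the marginal
            # likelihood; start from zero instead of failing
            beta0 = np.zeros(X.shape[1])
        start = np.append(beta0, fixed_log_sigma if fixed_log_sigma is not None else np.log(0.5))
    p = X.shape[1]
    state = {"u": np.zeros(G)}

    def nll(theta):
        log_sigma = fixed_log_sigma if fixed_log_sigma is not None else theta[p]
        ll, u_hat = marginal_loglik(
            theta[:p], log_sigma, X, y, codes, G, nodes, weights, state["u"]
        )
        state["u"] = u_hat
        return -ll

    sigma_bounds = (
        (fixed_log_sigma, fixed_log_sigma)
        if fixed_log_sigma is not None
        else (np.log(1e-6), np.log(20.0))
    )
    res = minimize(
        nll,
        start,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [sigma_bounds],
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and abs(res.fun) > 0:
        # L-BFGS-B occasionally stalls on the flat log-sigma direction;
        # retry once with Nelder-Mead polish from the best point
        res2 = minimize(nll, res.x, method="Nelder-Mead", options={"maxiter": 2000, "fatol": 1e-9})
        if res2.fun <= res.fun:
            res = res2
    if not np.isfinite(res.fun):
        raise ConvergenceError("mixed-model marginal likelihood not finite at optimum")

    theta = res.x
    if fixed_log_sigma is not None:
        theta[p] = fixed_log_sigma
    beta, sigma = theta[:p], float(np.exp(theta[p]))
    boundary = sigma < _SIGMA_FLOOR

    # fixed-effect covariance from a finite-difference Hessian
    free = list(range(p)) if (boundary or fixed_log_sigma is not None) else list(range(p + 1))
    H = _num_hessian(nll, theta, free)
    cov_all = np.linalg.inv(H)
    cov = cov_all[:p, :p]
    sigma_se = float(np.sqrt(cov_all[p, p]) * sigma) if not boundary else np.nan

    return ModelFit(
        family="MLR",
        names=list(names),
        coef=beta,
        cov=cov,
        loglik=-float(res.fun),
        converged=bool(res.success or np.max(np.abs(_num_grad(nll, theta))) < 5e-3),
        n_iter=int(res.nit) if hasattr(res, "nit") else -1,
        random_effect_sd=0.0 if boundary else sigma,
        spec=spec,
        levels=levels,
        extras={
            "boundary": boundary,
            "n_quadrature_nodes": n_quadrature_nodes,
            "n_groups": G,
            "random_effect_sd_se": sigma_se,
            "group_modes": state["u"],
        },
    )


def _num_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    for i in range(x.size):
        h = eps * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def _num_hessian(f, x, free, eps=1e-4):
    m = len(free)
    H = np.zeros((len(x), len(x)))
    f0 = f(x)
    steps = [eps * (1.0 + abs(x[i])) for i in free]
    for a in range(m):
        i, hi = free[a], steps[a]
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        H[i, i] = (f(xp) - 2 * f0 + f(xm)) / hi**2
        for b in range(a + 1, m):
            j, hj = free[b], steps[b]
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[i] += hi
            xpp[j] += hj
            xpm[i] += hi
            xpm[j] -= hj
            xmp[i] -= hi
            xmp[j] += hj
            xmm[i] -= hi
            xmm[j] -= hj
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * hi * hj)
    # keep the full matrix invertible when sigma is on the boundary
    for i in range(len(x)):
        if H[i, i] == 0:
            H[i, i] = 1.0
    return H
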