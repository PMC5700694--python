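"""Additive logistic model: parametric factor terms plus one penalized
cubic regression spline per continuous term.

Each smooth uses a 10-function cubic B-spline basis with knots at
empirical quantiles of the training data, a second-derivative
(curvature) penalty, and a sum-to-zero constraint for identifiability
with the global intercept.  The penalty's null space is the centred
linear function, so an infinite penalty collapses a smooth to a straight
line.  Smoothing weights are chosen by generalized cross-validation
(GCV) over a fixed log-spaced grid, searched over the product grid when
there are several smooth terms.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import block_diag, null_space
from scipy.special import expit

from .errors import DomainError
from .logistic import irls
from .model import ModelFit, ModelSpec, build_design_matrix

N_KNOTS = 10  # basis functions per smooth
DEFAULT_GRID = np.logspace(-2.0, 8.0, 11)


def _knot_vector(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    n_interior = n_basis - degree - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    lo -= 1e-8 * (span + 1)
    hi += 1e-8 * (span + 1)
    qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    return np.concatenate([[lo] * (degree + 1), qs, [hi] * (degree + 1)])


def _basis(x: np.ndarray, t: np.ndarray, degree: int = 3) -> np.ndarray:
    # clamp outside the training range: constant extrapolation of the
    # boundary basis values (documented behaviour for prediction)
    xc = np.clip(x, np.nextafter(t[0], t[-1]), np.nextafter(t[-1], t[0]))
    return BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()


def _curvature_penalty(t: np.ndarray, degree: int = 3) -> np.ndarray:
    """Exact integral of products of second derivatives of the basis."""
    n_basis = len(t) - degree - 1
    # second derivatives of cubic B-splines are piecewise linear, so
    # two-point Gauss-Legendre per knot span integrates products exactly
    gl_x = np.array([-1, 1]) / np.sqrt(3.0)
    pts, wts = [], []
    for a, b in zip(t[degree:-degree - 1], t[degree + 1 : -degree]):
        if b > a:
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            pts.extend(mid + half * gl_x)
            wts.extend([half, half])
    pts, wts = np.asarray(pts), np.asarray(wts)
    D2 = np.column_stack(
        [BSpline(t, np.eye(n_basis)[i], degree).derivative(2)(pts) for i in range(n_basis)]
    )
    return (D2 * wts[:, None]).T @ D2


class _SmoothState:
    """Per-term basis and constraint state needed for prediction."""

    def __init__(self, term: str, x: np.ndarray, n_basis: int):
        n_distinct = np.unique(x).size
        if n_distinct < 10:
            raise DomainError(f"smooth term {term!r} has only {n_distinct} distinct values")
        if n_distinct < n_basis + 4:
            warnings.warn(f"reducing knots for smooth term {term!r}", stacklevel=3)
            n_basis = max(5, n_distinct - 4)
        self.term = term
        self.t = _knot_vector(x, n_basis)
        B = _basis(x, self.t)
        self.Z = null_space(B.mean(axis=0, keepdims=True))
        self.S = self.Z.T @ _curvature_penalty(self.t) @ self.Z
        self.n_col = self.Z.shape[1]

    def design(self, x: np.ndarray) -> np.ndarray:
        return _basis(x, self.t) @ self.Z


def _assemble(df, spec: ModelSpec, levels, smooths):
    Xp, y, names, levels = build_design_matrix(
        df, spec.with_terms(smooth_terms=(), interaction_terms=()), levels
    )
    blocks, slices, pos = [Xp], {}, Xp.shape[1]
    for st in smooths:
        Bz = st.design(df[st.term].to_numpy(dtype=float))
        blocks.append(Bz)
        slices[st.term] = slice(pos, pos + st.n_col)
        names = names + [f"s({st.term}).{i+1}" for i in range(st.n_col)]
        pos += st.n_col
    return np.column_stack(blocks), y, names, levels, slices


def _penalty_matrix(p_total, smooths, slices, lambdas):
    P = np.zeros((p_total, p_total))
    for st in smooths:
        sl = slices[st.term]
        P[sl, sl] = lambdas[st.term] * st.S
    return P


def _edf(X, coef, P):
    eta = X @ coef
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X.T * w) @ X
    F = np.linalg.solve(XtWX + P, XtWX)
    return np.diag(F)


def fit_gam(
    df,
    spec: ModelSpec,
    levels=None,
    lambdas=None,
    lambda_grid=DEFAULT_GRID,
    n_basis: int = N_KNOTS,
) -> ModelFit:
    """Fit the additive logistic model, selecting smoothness by GCV.

    ``lambdas`` (a dict term -> weight) bypasses the GCV search, which is
    how the infinite-penalty limit is exercised.
    """
    smooths = [
        _SmoothState(term, df[term].to_numpy(dtype=float), n_basis)
        for term in spec.smooth_terms
    ]
    X, y, names, levels, slices = _assemble(df, spec, levels, smooths)
    n, p = X.shape

    def fit_at(lam):
        P = _penalty_matrix(p, smooths, slices, lam)
        coef, cov, ll, conv, it = irls(X, y, penalty=P)
        edf = float(np.sum(_edf(X, coef, P)))
        gcv = n * (-2.0 * ll) / (n - edf) ** 2
        return coef, cov, ll, conv, it, edf, gcv, P

    if lambdas is None:
        best = None
        terms = [st.term for st in smooths]
        for combo in itertools.product(lambda_grid, repeat=len(terms)):
            lam = dict(zip(terms, combo))
            out = fit_at(lam)
            if best is None or out[6] < best[1][6]:
                best = (lam, out)
        lambdas, (coef, cov, ll, conv, it, edf, gcv, P) = best
    else:
        coef, cov, ll, conv, it, edf, gcv, P = fit_at(lambdas)

    edf_diag = _edf(X, coef, P)
    edf_terms = {st.term: float(np.sum(edf_diag[slices[st.term]])) for st in smooths}
    return ModelFit(
        family="GAM",
        names=names,
        coef=coef,
        cov=cov,
        loglik=ll,
        converged=conv,
        n_iter=it,
        spec=spec,
        levels=levels,
        extras={
            "smooths": smooths,
            "slices": slices,
            "lambdas": dict(lambdas),
            "edf_total": float(np.sum(edf_diag)),
            "edf_terms": edf_terms,
            "gcv": gcv,
        },
    )


def predict_gam(fit: ModelFit, records) -> np.ndarray:
    Xp, _, names, _ = build_design_matrix(
        records,
        fit.spec.with_terms(smooth_terms=(), interaction_terms=()),
        fit.levels,
        outcome_col="__none__",
    )
    blocks = [Xp]
    for st in fit.extras["smooths"]:
        blocks.append(st.design(records[st.term].to_numpy(dtype=float)))
    X = np.column_stack(blocks)
    return expit(X @ fit.coef)
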