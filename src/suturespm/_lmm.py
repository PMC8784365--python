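"""Random-intercept linear mixed model, fitted by REML.

Model: y = X beta + b_g + e, with one random intercept b_g ~ N(0, s_u) per
grouping unit (participant) and independent residuals whose variance may
differ by an observation-level *cell* (e.g. segment-by-skill), e_i ~
N(0, s_{cell(i)}).  The marginal covariance of a participant block is

    V_g = diag(s_cell) + s_u * 1 1',

inverted in closed form via the rank-one (Sherman-Morrison) update, so the
REML criterion costs O(n p^2) per evaluation.  Variances are optimised on
the log scale with L-BFGS-B.

Satterthwaite degrees of freedom for a single-df contrast l'beta are
computed numerically: df = 2 g^2 / (grad_g' A grad_g) with g(theta) =
l' (X'V^-1X)^-1 l, the gradient by central differences over the
log-variance parameters, and A the inverse observed REML information
(finite-difference Hessian).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = ["LMMFit", "fit_random_intercept", "satterthwaite_df", "wald_f"]

_LOGVAR_BOUNDS = (-25.0, 10.0)


@dataclass
class LMMFit:
    """REML fit of a random-intercept model with per-cell residual variances."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_participant: float
    sigma2_residual: dict[str, float]
    theta: np.ndarray  # log variances: [participant, cell_0, cell_1, ...]
    neg2_reml: float
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    _X: np.ndarray = field(repr=False)
    _y: np.ndarray = field(repr=False)
    _slices: list = field(repr=False)
    _cell_codes: np.ndarray = field(repr=False)


def _pieces(theta: np.ndarray, X: np.ndarray, y: np.ndarray, slices, cell_codes):
    """(0.5 * -2 REML loglik, beta, inv(X'V^-1X)) at the given log variances."""
    s_u = np.exp(theta[0])
    s_cells = np.exp(theta[1:])
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for sl in slices:
        Xg = X[sl]
        yg = y[sl]
        d = s_cells[cell_codes[sl]]
        dinv = 1.0 / d
        a = float(dinv.sum())
        w = s_u / (1.0 + s_u * a)
        Xd = Xg * dinv[:, None]
        u = Xd.sum(axis=0)
        ys = float(yg @ dinv)
        XtViX += Xg.T @ Xd - w * np.outer(u, u)
        XtViy += Xd.T @ yg - w * u * ys
        ytViy += float(yg @ (yg * dinv)) - w * ys * ys
        logdet += float(np.log(d).sum()) + np.log1p(s_u * a)
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - float(beta @ XtViy)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    neg2 = logdet + logdet_xvx + quad
    return 0.5 * neg2, beta, np.linalg.inv(XtViX)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    cells: Optional[Sequence] = None,
) -> LMMFit:
    """Fit by REML; ``cells`` labels each observation's residual-variance cell.

    ``cells=None`` gives the ordinary homoscedastic random-intercept model.
    A fit whose participant variance collapses to the boundary is flagged
    ``singular`` (not an error).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y have different lengths")
    groups = np.asarray(groups)
    if cells is None:
        cells = np.zeros(n, dtype=int)
        cell_names = ["residual"]
        cell_codes = cells
    else:
        cells = np.asarray(cells)
        uniq, cell_codes = np.unique(cells, return_inverse=True)
        cell_names = [str(c) for c in uniq]

    # sort into contiguous participant blocks
    order = np.argsort(groups, kind="stable")
    Xs, ys_, gs, cs = X[order], y[order], groups[order], cell_codes[order]
    slices = []
    start = 0
    for i in range(1, n + 1):
        if i == n or gs[i] != gs[start]:
            slices.append(slice(start, i))
            start = i

    # start values from the OLS residual variance, split evenly
    beta_ols, *_ = np.linalg.lstsq(Xs, ys_, rcond=None)
    resid = ys_ - Xs @ beta_ols
    v0 = max(float(resid @ resid) / max(n - X.shape[1], 1), 1e-10)
    theta0 = np.full(1 + len(cell_names), np.log(v0 / 2.0))

    def objective(theta):
        try:
            val, _, _ = _pieces(theta, Xs, ys_, slices, cs)
        except np.linalg.LinAlgError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=[_LOGVAR_BOUNDS] * len(theta0),
    )
    theta = res.x
    obj, beta, cov_beta = _pieces(theta, Xs, ys_, slices, cs)
    s_u = float(np.exp(theta[0]))
    s_res = {name: float(np.exp(theta[1 + i])) for i, name in enumerate(cell_names)}
    mean_res = float(np.mean(list(s_res.values())))
    singular = s_u < 1e-6 * mean_res or theta[0] <= _LOGVAR_BOUNDS[0] + 1e-6
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_participant=s_u,
        sigma2_residual=s_res,
        theta=theta,
        neg2_reml=2.0 * obj,
        converged=bool(res.success),
        singular=singular,
        n_obs=n,
        n_groups=len(slices),
        _X=Xs,
        _y=ys_,
        _slices=slices,
        _cell_codes=cs,
    )


def satterthwaite_df(fit: LMMFit, contrast: np.ndarray, h: float = 1e-4) -> float:
    """Satterthwaite degrees of freedom for the scalar contrast l'beta.

    Falls back to the between-participant df (n_groups - 2) when the
    curvature estimate is not positive (boundary fits).
    """
    l = np.asarray(contrast, dtype=float)
    k = len(fit.theta)

    def g(theta):
        _, _, cov = _pieces(theta, fit._X, fit._y, fit._slices, fit._cell_codes)
        return float(l @ cov @ l)

    def f(theta):
        val, _, _ = _pieces(theta, fit._X, fit._y, fit._slices, fit._cell_codes)
        return val

    grad = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        grad[i] = (g(fit.theta + e) - g(fit.theta - e)) / (2 * h)

    # observed REML information (finite-difference Hessian of the objective)
    H = np.zeros((k, k))
    f0 = f(fit.theta)
    hh = 1e-3
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = hh
        for j in range(i, k):
            ej = np.zeros(k)
            ej[j] = hh
            if i == j:
                H[i, i] = (f(fit.theta + ei) - 2 * f0 + f(fit.theta - ei)) / hh**2
            else:
                H[i, j] = H[j, i] = (
                    f(fit.theta + ei + ej)
                    - f(fit.theta + ei)
                    - f(fit.theta + ej)
                    + f0
                ) / hh**2

    fallback = max(fit.n_groups - 2, 1)
    try:
        A = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return float(fallback)
    denom = float(grad @ A @ grad)
    g0 = g(fit.theta)
    if denom <= 0 or not np.isfinite(denom) or g0 <= 0:
        return float(fallback)
    df = 2.0 * g0 * g0 / denom
    return float(np.clip(df, 1.0, fit.n_obs - fit._X.shape[1]))


def wald_f(fit: LMMFit, L: np.ndarray, ddf: float) -> tuple[float, float]:
    """Wald F test of L beta = 0 with the given denominator df; returns (F, p)."""
    from scipy import stats

    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    Lb = L @ fit.beta
    M = L @ fit.cov_beta @ L.T
    F = float(Lb @ np.linalg.solve(M, Lb)) / q
    p = float(stats.f.sf(F, q, ddf))
    return F, p
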