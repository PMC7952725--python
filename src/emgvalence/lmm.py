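"""Maximum-likelihood linear mixed model with random intercept and slope.

Two-level model for observations i nested in participants j:

    y_ij = x_ij' beta + z_ij' b_j + e_ij,
    b_j ~ N(0, Psi),  e_ij ~ N(0, sigma^2),  z_ij = (1, x_ij)

Estimation profiles out ``beta`` and ``sigma^2`` analytically and minimizes
the profiled ML deviance over the relative covariance factor ``Lambda``
(``Psi = sigma^2 * Lambda Lambda'``), parameterized by its log-Cholesky
coordinates so positive semidefiniteness is automatic. Because ``z`` has
only two columns, every deviance evaluation reduces — via the Woodbury
identity — to 2x2 algebra on per-group cross-products, independent of the
number of observations per participant. A quasi-Newton search from a fixed
two-point multi-start gives deterministic fits; standard errors come from
the observed information of the profiled GLS problem at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

_SIGMA2_FLOOR_REL = 1e-12
_THETA_STARTS = (
    np.array([np.log(0.5), np.log(0.5), 0.0]),
    np.array([np.log(0.05), np.log(0.05), 0.0]),
)
_THETA_BOUNDS = [(-12.0, 8.0), (-12.0, 8.0), (-30.0, 30.0)]


@dataclass
class GroupStats:
    """Per-participant cross-products; all that the deviance needs."""

    label: object
    n: int
    ZtZ: np.ndarray
    ZtX: np.ndarray
    Zty: np.ndarray
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float


@dataclass
class LMMFit:
    """ML fit of the random-intercept/random-slope model."""

    beta: np.ndarray  # fixed effects (intercept, slope, covariates...)
    cov_beta: np.ndarray
    sigma2: float
    cov_re: np.ndarray  # Psi, 2x2 (intercept, slope)
    theta: np.ndarray
    llf: float
    converged: bool
    boundary_sigma: bool
    n_obs: int
    n_groups: int
    group_labels: list = field(default_factory=list)
    random_effects: dict = field(default_factory=dict)  # label -> (b0, b1)
    fitted: np.ndarray | None = None
    resid: np.ndarray | None = None  # conditional residuals
    resid_marginal: np.ndarray | None = None
    optimizer_message: str = ""

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _group_stats(y, X, x_rand, groups) -> list[GroupStats]:
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    xr = np.asarray(x_rand, float)
    groups = np.asarray(groups)
    stats = []
    for g in pd_unique(groups):
        m = groups == g
        Z = np.column_stack([np.ones(m.sum()), xr[m]])
        Xg, yg = X[m], y[m]
        stats.append(
            GroupStats(
                label=g,
                n=int(m.sum()),
                ZtZ=Z.T @ Z,
                ZtX=Z.T @ Xg,
                Zty=Z.T @ yg,
                XtX=Xg.T @ Xg,
                Xty=Xg.T @ yg,
                yty=float(yg @ yg),
            )
        )
    return stats


def pd_unique(a: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(a, return_index=True)
    return a[np.sort(idx)]


def _lambda_of(theta: np.ndarray) -> np.ndarray:
    return np.array([[np.exp(theta[0]), 0.0], [theta[2], np.exp(theta[1])]])


def _profiled_pieces(theta, stats, p):
    """Accumulate GLS pieces A, c, yy and sum of log|V_j| for given theta."""
    L = _lambda_of(theta)
    A = np.zeros((p, p))
    c = np.zeros(p)
    yy = 0.0
    logdet = 0.0
    Ws = []
    for s in stats:
        M = np.eye(2) + L.T @ s.ZtZ @ L
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        logdet += ld
        W = L @ np.linalg.solve(M, L.T)
        Ws.append(W)
        A += s.XtX - s.ZtX.T @ W @ s.ZtX
        c += s.Xty - s.ZtX.T @ W @ s.Zty
        yy += s.yty - s.Zty @ W @ s.Zty
    return A, c, yy, logdet, Ws


def _deviance(theta, stats, n, p, scale):
    pieces = _profiled_pieces(theta, stats, p)
    if pieces is None:
        return 1e12
    A, c, yy, logdet, _ = pieces
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return 1e12
    q = max(yy - beta @ c, _SIGMA2_FLOOR_REL * n * scale)
    return n * np.log(2.0 * np.pi * q / n) + logdet + n


def fit_random_slope_ml(
    y,
    X,
    x_rand,
    groups,
    starts: tuple[np.ndarray, ...] = _THETA_STARTS,
    ftol: float = 1e-12,
    gtol: float = 1e-8,
) -> LMMFit:
    """Fit the two-level random-intercept/slope model by ML.

    Parameters
    ----------
    y : (n,) response (standardized EMG envelope).
    X : (n, p) fixed-effects design; column 0 the intercept, column 1 the
        random-slope variable, optional level-2 covariates after.
    x_rand : (n,) the variable carrying the random slope (valence).
    groups : (n,) participant labels.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    # center the random-slope variable for a well-conditioned covariance
    # search; the model family is translation-equivariant, so estimates are
    # mapped back exactly below
    xbar = float(np.mean(x_rand))
    xr_c = np.asarray(x_rand, float) - xbar
    stats = _group_stats(y, X, xr_c, groups)
    m = len(stats)
    if m < 3:
        raise ValueError(f"need >= 3 participants, got {m}")
    for s in stats:
        if s.n < 3:
            raise ValueError(f"participant {s.label!r} has only {s.n} observations (need >= 3)")
        if np.allclose(s.ZtZ[0, 1] ** 2, s.n * s.ZtZ[1, 1]):
            warnings.warn(
                f"participant {s.label!r}: predictor constant within participant; "
                "contributes to intercept terms only",
                stacklevel=2,
            )
    scale = float(np.var(y)) + 1.0

    attempts = []
    for t0 in starts:
        attempts.append(
            optimize.minimize(
                _deviance,
                t0,
                args=(stats, n, p, scale),
                method="L-BFGS-B",
                bounds=_THETA_BOUNDS,
                options={"ftol": ftol, "gtol": gtol, "maxiter": 500},
            )
        )
    best = min(attempts, key=lambda r: r.fun)
    polish = optimize.minimize(
        _deviance,
        best.x,
        args=(stats, n, p, scale),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    attempts.append(polish)
    if polish.fun < best.fun:
        best = polish
    # converged if the chosen optimum came from (or ties, within tolerance,
    # with) a successful optimizer run
    success_funs = [r.fun for r in attempts if r.success]
    converged = bool(best.success) or (
        bool(success_funs) and best.fun >= min(success_funs) - 1e-6
    )
    theta = best.x
    pieces = _profiled_pieces(theta, stats, p)
    A, c, yy, logdet, Ws = pieces
    beta = np.linalg.solve(A, c)
    q = yy - beta @ c
    boundary = q <= _SIGMA2_FLOOR_REL * n * scale * 10
    q = max(q, _SIGMA2_FLOOR_REL * n * scale)
    sigma2 = q / n
    L = _lambda_of(theta)
    # map the covariance back to the uncentered basis: u0 = u0' - xbar*u1
    T = np.array([[1.0, -xbar], [0.0, 1.0]])
    cov_re = sigma2 * (T @ (L @ L.T) @ T.T)
    cov_beta = sigma2 * np.linalg.inv(A)
    llf = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)

    # BLUPs and conditional residuals (computed in the centered basis, the
    # reported intercept deviation is mapped back)
    re: dict = {}
    yv = np.asarray(y, float)
    garr = np.asarray(groups)
    fitted = np.empty(n)
    resid_marg = np.empty(n)
    for s, W in zip(stats, Ws):
        u = s.Zty - s.ZtX @ beta  # Z' r, r the marginal residual
        zvr = u - s.ZtZ @ (W @ u)  # Z' V^{-1} r
        b = (L @ L.T) @ zvr
        re[s.label] = (float(b[0] - xbar * b[1]), float(b[1]))
        msk = garr == s.label
        Xb = X[msk] @ beta
        resid_marg[msk] = yv[msk] - Xb
        fitted[msk] = Xb + b[0] + b[1] * xr_c[msk]
    resid = yv - fitted

    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        cov_re=cov_re,
        theta=theta,
        llf=float(llf),
        converged=converged,
        boundary_sigma=bool(boundary),
        n_obs=n,
        n_groups=m,
        group_labels=[s.label for s in stats],
        random_effects=re,
        fitted=fitted,
        resid=resid,
        resid_marginal=resid_marg,
        optimizer_message=str(best.message),
    )


def ols_loglike(y, X) -> float:
    """ML log-likelihood of the nested ordinary regression (no random part)."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    s2 = max(float(r @ r) / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
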