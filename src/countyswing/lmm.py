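"""Linear mixed model with a random intercept and one random slope per group.

The model, for county i in state s,

    y_i = x_i' beta + u_s + v_s * z_i + e_i,
    (u_s, v_s) ~ N(0, G),   G = [[s_u^2, rho*s_u*s_v], [., s_v^2]],
    e_i ~ N(0, sigma^2 / w_i),

is fit by maximum likelihood with beta profiled out: for a candidate set of
variance parameters the GLS estimate of beta is closed-form, so only the four
parameters (log s_u, log s_v, atanh rho, log sigma) are optimized numerically.
ML (not REML) is used so that variance-explained decompositions and nested
model comparisons are coherent.

Optional observation weights enter as residual precision weights (variance
sigma^2 / w_i), the convention of classical weighted least squares; weights
are normalized to mean 1 so sigma^2 keeps its unweighted scale. With all
weights equal the fit is numerically identical to the unweighted fit.

The random-slope covariate is scaled to unit variance internally for
optimizer conditioning and the variance components are rescaled back on exit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMResult:
    """Fitted random-intercept / random-slope mixed model."""

    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma_u2: float          # state intercept variance
    sigma_v2: float          # state slope variance (original covariate scale)
    rho: float               # intercept-slope correlation
    sigma_e2: float          # residual variance
    loglik: float
    ranef: pd.DataFrame      # per-group BLUPs: columns intercept, slope
    fitted_fixed: np.ndarray
    fitted_total: np.ndarray
    r2_fixed: float          # var(X beta) / var(y)
    r2_total: float          # var(X beta + Z b) / var(y)
    converged: bool
    diagonal_fallback: bool = False
    n_obs: int = 0
    n_groups: int = 0
    cov_beta: np.ndarray = field(default=None, repr=False)


def _group_indices(groups: np.ndarray) -> dict:
    idx = {}
    order = pd.unique(groups)
    for g in order:
        idx[g] = np.flatnonzero(groups == g)
    return idx


def _nll_and_beta(theta, y, X, z, gidx, dinv, diagonal):
    """Profiled negative log-likelihood; returns (nll, beta, cov_beta, Vinfo)."""
    log_su, log_sv, zrho, log_se = theta
    su, sv, se2 = np.exp(log_su), np.exp(log_sv), np.exp(2.0 * log_se)
    rho = 0.0 if diagonal else np.tanh(zrho)
    G = np.array([[su * su, rho * su * sv], [rho * su * sv, sv * sv]])

    p = X.shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    logdet = 0.0
    chunks = []
    for g, ix in gidx.items():
        Zg = np.column_stack([np.ones(ix.size), z[ix]])
        V = Zg @ G @ Zg.T + np.diag(se2 * dinv[ix])
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        Xi = np.linalg.solve(L, X[ix])         # L^-1 X
        yi = np.linalg.solve(L, y[ix])
        A += Xi.T @ Xi
        bvec += Xi.T @ yi
        chunks.append((g, ix, L, G, Zg))
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = cov_beta @ bvec

    quad = 0.0
    for g, ix, L, _, _ in chunks:
        ri = np.linalg.solve(L, y[ix] - X[ix] @ beta)
        quad += ri @ ri
    n = y.size
    nll = 0.5 * (logdet + quad + n * _LOG2PI)
    return nll, beta, cov_beta, chunks


def fit_lmm(
    y: np.ndarray,
    X: pd.DataFrame,
    slope_covariate: np.ndarray,
    groups: np.ndarray,
    weights: np.ndarray | None = None,
    diagonal: bool = False,
) -> LMMResult:
    """Fit the random-intercept / random-slope model by profiled ML.

    Parameters
    ----------
    y, X
        Outcome and fixed-effect design (X should include an intercept column).
    slope_covariate
        The covariate carrying the per-group random slope (typically also a
        column of X).
    groups
        Group labels (states), one per row.
    weights
        Optional positive residual precision weights (e.g. county population);
        normalized internally to mean 1.
    diagonal
        Force a diagonal random-effects covariance (rho = 0).
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    z = np.asarray(slope_covariate, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    if n != Xm.shape[0] or n != z.size or n != groups.size:
        raise ValueError("y, X, slope_covariate, groups must have equal length")
    gidx = _group_indices(groups)
    if len(gidx) < 2:
        raise ValueError("at least 2 groups are required")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")

    if weights is None:
        dinv = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.mean()
        dinv = 1.0 / w

    sz = z.std()
    if sz == 0:
        raise ValueError("slope covariate is constant; no random slope identifiable")
    zs = z / sz

    sd_y = max(y.std(), 1e-8)
    theta0 = np.log([0.5 * sd_y, 0.25 * sd_y, 1.0, 0.8 * sd_y])
    theta0 = np.array([theta0[0], theta0[1], 0.0, theta0[3]])
    bounds = [(np.log(sd_y) - 12, np.log(sd_y) + 4)] * 2 + [(-5, 5)] + [
        (np.log(sd_y) - 8, np.log(sd_y) + 4)]

    def obj(theta):
        return _nll_and_beta(theta, y, Xm, zs, gidx, dinv, diagonal)[0]

    best = None
    starts = [theta0, theta0 + np.array([0.7, 0.7, 0.0, -0.3])]
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(obj, s, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    res = best

    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError("mixed-model optimization failed to produce a finite likelihood")

    nll, beta, cov_beta, chunks = _nll_and_beta(res.x, y, Xm, zs, gidx, dinv, diagonal)
    log_su, log_sv, zrho, log_se = res.x
    rho = 0.0 if diagonal else float(np.tanh(zrho))
    fallback = False
    if not diagonal and abs(rho) > 0.9999:
        logger.warning("random-effects covariance is singular (|rho| ~ 1); refitting with a "
                       "diagonal covariance")
        out = fit_lmm(y, X, slope_covariate, groups, weights=weights, diagonal=True)
        out.diagonal_fallback = True
        return out

    su = float(np.exp(log_su))
    sv_int = float(np.exp(log_sv))
    se2 = float(np.exp(2 * log_se))
    G = np.array([[su**2, rho * su * sv_int], [rho * su * sv_int, sv_int**2]])

    # BLUPs: b_g = G Z_g' V_g^-1 r_g, then unscale the slope component.
    resid = y - Xm @ beta
    ranef_rows = {}
    for g, ix, L, _, Zg in chunks:
        ri = np.linalg.solve(L.T, np.linalg.solve(L, resid[ix]))
        b = G @ Zg.T @ ri
        ranef_rows[g] = (b[0], b[1] / sz)
    ranef = pd.DataFrame.from_dict(ranef_rows, orient="index",
                                   columns=["intercept", "slope"])
    ranef.index.name = "group"

    g_lookup = ranef["intercept"].to_dict()
    s_lookup = ranef["slope"].to_dict()
    u = np.array([g_lookup[g] for g in groups])
    v = np.array([s_lookup[g] for g in groups])
    fitted_fixed = Xm @ beta
    fitted_total = fitted_fixed + u + v * z

    # variance-of-predictions R^2; in the weighted metric when weights given
    wnorm = 1.0 / dinv
    def _wvar(x):
        mu = np.average(x, weights=wnorm)
        return np.average((x - mu) ** 2, weights=wnorm)
    var_y = _wvar(y)
    r2_fixed = float(_wvar(fitted_fixed) / var_y) if var_y > 0 else np.nan
    r2_total = float(_wvar(fitted_total) / var_y) if var_y > 0 else np.nan

    se_beta = np.sqrt(np.diag(cov_beta))
    zstat = beta / se_beta
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))

    return LMMResult(
        beta=pd.Series(beta, index=names, name="coef"),
        se=pd.Series(se_beta, index=names, name="se"),
        pvalues=pd.Series(pvals, index=names, name="p"),
        sigma_u2=su**2,
        sigma_v2=(sv_int / sz) ** 2,
        rho=rho,
        sigma_e2=se2,
        loglik=-nll,
        ranef=ranef,
        fitted_fixed=fitted_fixed,
        fitted_total=fitted_total,
        r2_fixed=r2_fixed,
        r2_total=r2_total,
        converged=bool(res.success),
        diagonal_fallback=fallback,
        n_obs=n,
        n_groups=len(gidx),
        cov_beta=cov_beta,
    )
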