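"""Multilevel left-censored Bayesian imputation of suppressed death counts.

Small-area rare-cause counts published under a disclosure rule are
interval-censored: a suppressed cell says only that its count lies in
[lower, threshold - 1]. The model here is the minimal multilevel structure
consistent with that censoring:

    y_ij ~ Poisson(lambda_ij),
    log lambda_ij = log PY_i + alpha + gamma * 1[period j = later] + s_{state(i)} + c_i,
    s_k ~ N(0, sigma_s^2),  c_i ~ N(0, sigma_c^2),

with weakly informative normal priors on (alpha, gamma) and half-normal
priors on the random-effect scales. Censored cells contribute the Poisson
probability mass over the censoring interval; equivalently (and how it is
implemented) the censored counts are treated as latent variables and
resampled from the truncated Poisson each sweep of a Metropolis-within-Gibbs
sampler. Because the latent counts are integer draws from the truncated
posterior predictive, completed datasets are count-consistent for downstream
direct standardization.

The sampler is vectorized across chains. Two kinds of extra moves keep the
hierarchy mixing: translation moves that shift mass between the intercept
and a random-effect block (likelihood-invariant, they walk along the
posterior ridge), and non-centered rescaling moves that propose a new scale
while holding the standardized effects fixed (they cross the hierarchical
"funnel"). Split-chain R-hat is computed with arviz; exceeding the threshold
raises rather than returning silently bad imputations.

Downstream estimates computed once per completed dataset are pooled with
Rubin's combining rules (:func:`rubin_combine`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import CensoringRule, ImputationModelSpec

logger = logging.getLogger(__name__)


class ImputationConvergenceError(RuntimeError):
    """MCMC did not converge; carries the diagnostics that show it."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class ImputationSet:
    """M completed despair tables plus posterior summaries and diagnostics."""

    base: pd.DataFrame                 # long despair table, censored counts NaN
    imputed_counts: np.ndarray         # (M, n_censored) integer draws
    censored_cells: pd.DataFrame       # county_id/period keys, base row position
    summaries: pd.DataFrame            # per-cell posterior mean/sd/q05/q95
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return int(self.imputed_counts.shape[0])

    def dataset(self, m: int) -> pd.DataFrame:
        """The m-th completed table (observed cells identical across m)."""
        out = self.base.copy()
        if len(self.censored_cells):
            out.loc[self.censored_cells["row"].to_numpy(), "count"] = (
                self.imputed_counts[m].astype(float))
        out["suppressed"] = False
        return out

    def datasets(self):
        for m in range(self.m):
            yield self.dataset(m)


def _trunc_poisson_sample(lam: np.ndarray, lo: int, hi: int, rng) -> np.ndarray:
    """Sample truncated Poisson on {lo..hi}; lam of any shape."""
    k = np.arange(lo, hi + 1)
    logp = k * np.log(np.maximum(lam[..., None], 1e-300)) - lam[..., None] - gammaln(k + 1)
    logp -= logsumexp(logp, axis=-1, keepdims=True)
    cdf = np.cumsum(np.exp(logp), axis=-1)
    u = rng.random(lam.shape + (1,))
    return lo + np.sum(u > cdf, axis=-1).clip(0, hi - lo)


_LS_GRID = np.linspace(np.log(1e-3), np.log(10.0), 400)


def _sample_log_scale(ssq: np.ndarray, m: int, prior_sd: float, rng) -> np.ndarray:
    """Exact draw of log sigma given effects: inverse-cdf on a fixed grid.

    Density on the log scale: -m*ls - ssq/(2 e^{2ls}) - e^{2ls}/(2 prior^2) + ls
    (normal effects likelihood, half-normal prior, log-transform Jacobian).
    """
    g = _LS_GRID[None, :]
    lp = -m * g - ssq[:, None] / (2 * np.exp(2 * g)) - np.exp(2 * g) / (2 * prior_sd**2) + g
    lp -= lp.max(axis=1, keepdims=True)
    cdf = np.cumsum(np.exp(lp), axis=1)
    cdf /= cdf[:, -1:]
    idx = (rng.random((ssq.size, 1)) > cdf).sum(axis=1).clip(0, _LS_GRID.size - 1)
    step = _LS_GRID[1] - _LS_GRID[0]
    return _LS_GRID[idx] + rng.uniform(-0.5, 0.5, ssq.size) * step


def _prepare(table: pd.DataFrame):
    t = table.reset_index(drop=True)
    counties = t["county_id"].drop_duplicates().to_numpy()
    c_index = pd.Series(np.arange(counties.size), index=counties)
    states = t.drop_duplicates("county_id").set_index("county_id")["state_id"]
    state_names = states.drop_duplicates().to_numpy()
    s_index = pd.Series(np.arange(state_names.size), index=state_names)
    periods = np.sort(t["period"].unique())
    if len(periods) != 2:
        raise ValueError("imputation model expects exactly two periods")

    n = counties.size
    y = np.full((n, 2), np.nan)
    cens = np.zeros((n, 2), dtype=bool)
    py = np.zeros(n)
    rowpos = np.full((n, 2), -1, dtype=int)
    ci = c_index[t["county_id"]].to_numpy()
    pi = np.searchsorted(periods, t["period"].to_numpy())
    y[ci, pi] = t["count"].to_numpy()
    cens[ci, pi] = t["suppressed"].to_numpy(dtype=bool)
    py[ci] = t["person_years"].to_numpy()
    rowpos[ci, pi] = np.arange(len(t))
    if np.any(py <= 0):
        raise ValueError("person_years must be positive")
    if np.any(np.isnan(y) & ~cens):
        raise ValueError("missing count in a non-suppressed cell")
    state_of_county = s_index[states[counties]].to_numpy()

    obs_per_state = np.zeros(state_names.size, dtype=int)
    np.add.at(obs_per_state, np.repeat(state_of_county, 2)[~cens.ravel()], 1)
    if np.any(obs_per_state == 0):
        logger.warning("states with no observed cells: %s — their effects shrink to the prior",
                       state_names[obs_per_state == 0].tolist())
    return t, counties, state_names, state_of_county, y, cens, py, rowpos, periods


def fit_imputation_model(
    table: pd.DataFrame,
    rule: CensoringRule | None = None,
    spec: ImputationModelSpec | None = None,
) -> ImputationSet:
    """Fit the censored-count model and draw M completed datasets.

    Parameters
    ----------
    table
        Long-format rows for one cause stream: columns ``county_id, state_id,
        period, count, person_years, suppressed`` (count NaN where suppressed).
    rule
        Censoring rule (default: counts 1-9 suppressed).
    spec
        Model/MCMC settings; ``spec.seed`` controls reproducibility.
    """
    rule = rule or CensoringRule()
    spec = spec or ImputationModelSpec()
    spec.validate()
    lo, hi = rule.interval
    lo = max(lo, 0)
    t, counties, state_names, soc, y, cens, py, rowpos, periods = _prepare(table)
    n, S = counties.size, state_names.size
    ncens = int(cens.sum())
    cens_flat = np.flatnonzero(cens.ravel())
    ci_cens, pi_cens = np.divmod(cens_flat, 2)
    cells = pd.DataFrame({
        "county_id": counties[ci_cens],
        "period": periods[pi_cens],
        "row": rowpos[ci_cens, pi_cens],
    })
    base = t.copy()

    if ncens == 0:
        return ImputationSet(
            base=base, imputed_counts=np.empty((spec.m_datasets, 0), dtype=int),
            censored_cells=cells, summaries=pd.DataFrame(),
            diagnostics={"n_censored": 0, "max_rhat": 1.0})

    rng = np.random.default_rng(spec.seed)
    C = spec.chains

    # overdispersed chain starts around the crude log rate
    crude = np.log((np.nansum(np.nan_to_num(y), axis=1).sum() + 0.5)
                   / (2.0 * py.sum()))
    alpha = crude + rng.normal(0, 0.5, C)
    gamma = rng.normal(0, 0.3, C)
    s = rng.normal(0, 0.3, (C, S))
    c = rng.normal(0, 0.3, (C, n))
    ls_s = rng.normal(np.log(0.5), 0.3, C)
    ls_c = rng.normal(np.log(0.5), 0.3, C)
    y_aug = np.broadcast_to(np.nan_to_num(y, nan=float((lo + hi + 1) // 2)),
                            (C, n, 2)).copy()

    order = np.argsort(soc, kind="stable")
    starts = np.searchsorted(soc[order], np.arange(S))
    nk = np.diff(np.append(starts, n))
    perflag = np.array([0.0, 1.0])
    log_py = np.log(py)
    mu_a, sd_a = spec.prior_intercept
    mu_g, sd_g = spec.prior_period
    p_sd = spec.prior_scale_sd

    # proposal scales: per-coordinate for the effect blocks (states and
    # counties differ hugely in information), per-chain scalars otherwise
    tau = {"c": np.full((C, n), 0.4), "s": np.full((C, S), 0.3),
           "t_sc": np.full((C, S), 0.1)}
    tau.update({k: np.full(C, v) for k, v in
                (("a", 0.1), ("g", 0.1), ("ag", 0.1), ("t_c", 0.1), ("t_s", 0.1),
                 ("nc_s", 0.2), ("nc_c", 0.1))})
    acc = {k: np.zeros_like(v) for k, v in tau.items()}
    tries = {k: 0 for k in tau}

    def eta_of():
        e = (alpha[:, None, None] + gamma[:, None, None] * perflag[None, None, :]
             + s[:, soc][:, :, None] + c[:, :, None])
        return np.clip(e, -30.0, 30.0)

    def lam_of():
        return np.exp(log_py[None, :, None] + eta_of())

    def by_state(arr):  # (C, n) -> (C, S) sums
        return np.add.reduceat(arr[:, order], starts, axis=1)

    def ridge_and_scale_moves():
        nonlocal alpha, s, c, ls_s, ls_c
        sig_c = np.exp(ls_c)[:, None]
        sig_s = np.exp(ls_s)[:, None]

        # translation along the likelihood-invariant ridge: (alpha, c) and (alpha, s)
        d = rng.normal(0, 1, C) * tau["t_c"]
        dll = (((alpha - mu_a) ** 2 - (alpha + d - mu_a) ** 2) / (2 * sd_a**2)
               + ((c**2).sum(1) - ((c - d[:, None]) ** 2).sum(1)) / (2 * sig_c[:, 0] ** 2))
        ok = np.log(rng.random(C)) < dll
        alpha = np.where(ok, alpha + d, alpha)
        c = np.where(ok[:, None], c - d[:, None], c)
        acc["t_c"] += ok; tries["t_c"] += 1

        d = rng.normal(0, 1, C) * tau["t_s"]
        dll = (((alpha - mu_a) ** 2 - (alpha + d - mu_a) ** 2) / (2 * sd_a**2)
               + ((s**2).sum(1) - ((s - d[:, None]) ** 2).sum(1)) / (2 * sig_s[:, 0] ** 2))
        ok = np.log(rng.random(C)) < dll
        alpha = np.where(ok, alpha + d, alpha)
        s = np.where(ok[:, None], s - d[:, None], s)
        acc["t_s"] += ok; tries["t_s"] += 1

        # per-state exchange between the state effect and its counties' effects
        dk = rng.normal(0, 1, (C, S)) * tau["t_sc"]
        c_sq = by_state(c**2)
        c_sum = by_state(c)
        c_sq_new = c_sq - 2 * dk * c_sum + nk[None, :] * dk**2
        dll = ((s**2 - (s + dk) ** 2) / (2 * sig_s**2) + (c_sq - c_sq_new) / (2 * sig_c**2))
        ok = np.log(rng.random((C, S))) < dll
        s = np.where(ok, s + dk, s)
        c = c - np.where(ok, dk, 0.0)[:, soc]
        acc["t_sc"] += ok; tries["t_sc"] += 1

        # centered scale updates: the conditional p(log sigma | effects) is
        # univariate, so draw it exactly on a grid (no random-walk lag)
        ls_c = _sample_log_scale((c**2).sum(axis=1), c.shape[1], p_sd, rng)
        ls_s = _sample_log_scale((s**2).sum(axis=1), s.shape[1], p_sd, rng)

        # non-centered rescaling: hold standardized effects fixed, move the scale
        lam = lam_of()
        y_cnt = y_aug.sum(axis=2)
        for key in ("nc_s", "nc_c"):
            dl = rng.normal(0, 1, C) * tau[key]
            if key == "nc_s":
                vals, ls_cur = s, ls_s
                y_blk, lam_blk = by_state(y_cnt), by_state(lam.sum(axis=2))
            else:
                vals, ls_cur = c, ls_c
                y_blk, lam_blk = y_cnt, lam.sum(axis=2)
            delta = vals * np.expm1(dl)[:, None]
            dll = (y_blk * delta - lam_blk * np.expm1(np.clip(delta, -30, 30))).sum(axis=1)
            sig0, sig1 = np.exp(ls_cur), np.exp(ls_cur + dl)
            dll += (sig0**2 - sig1**2) / (2 * p_sd**2) + dl
            ok = np.log(rng.random(C)) < dll
            if key == "nc_s":
                s = np.where(ok[:, None], s * np.exp(dl)[:, None], s)
                ls_s = np.where(ok, ls_s + dl, ls_s)
                lam = lam * np.exp(np.where(ok[:, None], delta, 0.0))[:, soc, None]
            else:
                c = np.where(ok[:, None], c * np.exp(dl)[:, None], c)
                ls_c = np.where(ok, ls_c + dl, ls_c)
                lam = lam * np.exp(np.where(ok[:, None], delta, 0.0))[:, :, None]
            acc[key] += ok; tries[key] += 1

    n_keep = spec.draws
    keep = {k: np.empty((C, n_keep)) for k in
            ("alpha", "period_effect", "log_sigma_state", "log_sigma_county",
             "county_effect_mean")}
    keep_ycens = np.empty((C, n_keep, ncens), dtype=np.int16)

    total_iter = spec.warmup + n_keep
    for it in range(total_iter):
        warm = it < spec.warmup
        lam = lam_of()

        # 1) latent censored counts ~ truncated Poisson
        lam_cens = lam.reshape(C, -1)[:, cens_flat]
        y_aug.reshape(C, -1)[:, cens_flat] = _trunc_poisson_sample(lam_cens, lo, hi, rng)

        sig_c = np.exp(ls_c)[:, None]
        sig_s = np.exp(ls_s)[:, None]

        # 2) county intercepts: the Poisson conditional in exp(c_i) is Gamma,
        # so a Gamma independence proposal matches the likelihood exactly and
        # the acceptance ratio reduces to the normal prior (plus the +0.5
        # shape offset that keeps the proposal proper at zero counts)
        y_cnt = y_aug.sum(axis=2)
        lam_cnt = lam.sum(axis=2)
        B = lam_cnt * np.exp(-c)
        c_star = np.log(rng.gamma(y_cnt + 0.5) / B)
        dll = -0.5 * (c_star - c) + (c**2 - c_star**2) / (2 * sig_c**2)
        ok = np.log(rng.random((C, n))) < dll
        c = np.where(ok, c_star, c)
        lam_cnt = np.where(ok, B * np.exp(c), lam_cnt)
        acc["c"] += ok; tries["c"] += 1

        # 3) state intercepts: same Gamma independence proposal at state level
        y_state = by_state(y_cnt)
        lam_state = by_state(lam_cnt)
        B = lam_state * np.exp(-s)
        s_star = np.log(rng.gamma(y_state + 0.5) / B)
        dll = -0.5 * (s_star - s) + (s**2 - s_star**2) / (2 * sig_s**2)
        ok = np.log(rng.random((C, S))) < dll
        s = np.where(ok, s_star, s)
        acc["s"] += ok; tries["s"] += 1

        # 4) global intercept and period effect
        lam = lam_of()
        da = rng.normal(0, 1, C) * tau["a"]
        y_tot = y_aug.sum(axis=(1, 2))
        lam_tot = lam.sum(axis=(1, 2))
        dll = y_tot * da - lam_tot * np.expm1(da)
        dll += ((alpha - mu_a) ** 2 - (alpha + da - mu_a) ** 2) / (2 * sd_a**2)
        ok = np.log(rng.random(C)) < dll
        alpha = np.where(ok, alpha + da, alpha)
        lam = lam * np.exp(np.where(ok, da, 0.0))[:, None, None]
        acc["a"] += ok; tries["a"] += 1

        dg = rng.normal(0, 1, C) * tau["g"]
        y_15 = y_aug[:, :, 1].sum(axis=1)
        lam_15 = lam[:, :, 1].sum(axis=1)
        dll = y_15 * dg - lam_15 * np.expm1(dg)
        dll += ((gamma - mu_g) ** 2 - (gamma + dg - mu_g) ** 2) / (2 * sd_g**2)
        ok = np.log(rng.random(C)) < dll
        gamma = np.where(ok, gamma + dg, gamma)
        acc["g"] += ok; tries["g"] += 1

        # joint (alpha, gamma) move along their anti-correlated direction:
        # alpha + d, gamma - d changes only the earlier period's predictor
        dj = rng.normal(0, 1, C) * tau["ag"]
        lam = lam_of()
        y_00 = y_aug[:, :, 0].sum(axis=1)
        lam_00 = lam[:, :, 0].sum(axis=1)
        dll = y_00 * dj - lam_00 * np.expm1(dj)
        dll += ((alpha - mu_a) ** 2 - (alpha + dj - mu_a) ** 2) / (2 * sd_a**2)
        dll += ((gamma - mu_g) ** 2 - (gamma - dj - mu_g) ** 2) / (2 * sd_g**2)
        ok = np.log(rng.random(C)) < dll
        alpha = np.where(ok, alpha + dj, alpha)
        gamma = np.where(ok, gamma - dj, gamma)
        acc["ag"] += ok; tries["ag"] += 1

        # 5-7) ridge and scale moves are cheap relative to the count updates
        # and limit mixing, so they are repeated within each sweep
        for _ in range(3):
            ridge_and_scale_moves()

        if warm and (it + 1) % 50 == 0:
            for k in tau:
                rate = acc[k] / max(tries[k], 1)
                tau[k] *= np.exp(np.clip(rate - 0.35, -0.5, 0.5))
                acc[k][:] = 0.0
            tries = {k: 0 for k in tau}

        if not warm:
            j = it - spec.warmup
            keep["alpha"][:, j] = alpha
            keep["period_effect"][:, j] = gamma
            keep["log_sigma_state"][:, j] = ls_s
            keep["log_sigma_county"][:, j] = ls_c
            keep["county_effect_mean"][:, j] = c.mean(axis=1)
            keep_ycens[:, j, :] = y_aug.reshape(C, -1)[:, cens_flat]

    diagnostics = _diagnostics(keep, spec, ncens)

    flat = keep_ycens.reshape(C * n_keep, ncens)
    pick = np.linspace(0, flat.shape[0] - 1, spec.m_datasets).round().astype(int)
    imputed = flat[pick].astype(int)

    summaries = cells.copy()
    summaries["post_mean"] = flat.mean(axis=0)
    summaries["post_sd"] = flat.std(axis=0)
    summaries["q05"] = np.quantile(flat, 0.05, axis=0)
    summaries["q95"] = np.quantile(flat, 0.95, axis=0)

    if diagnostics["max_rhat"] > spec.rhat_threshold:
        raise ImputationConvergenceError(
            f"split-chain R-hat {diagnostics['max_rhat']:.3f} exceeds "
            f"{spec.rhat_threshold}; increase warmup/draws", diagnostics)

    return ImputationSet(base=base, imputed_counts=imputed, censored_cells=cells,
                         summaries=summaries, diagnostics=diagnostics)


def _diagnostics(params: dict, spec: ImputationModelSpec, ncens: int) -> dict:
    import arviz as az

    rhat = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, draws in params.items():
            if draws.shape[0] >= 2:
                rhat[name] = float(np.asarray(
                    az.rhat(az.convert_to_dataset(draws))["x"].values).max())
            else:
                rhat[name] = float("nan")
    vals = [v for v in rhat.values() if np.isfinite(v)]
    return {"rhat": rhat, "max_rhat": max(vals) if vals else 1.0,
            "n_censored": ncens, "chains": spec.chains, "draws": spec.draws,
            "warmup": spec.warmup}


@dataclass(frozen=True)
class RubinResult:
    """Pooled multiple-imputation estimate."""

    estimate: float
    total_variance: float
    within_variance: float
    between_variance: float
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def rubin_combine(estimates, within_variances) -> RubinResult:
    """Pool M point estimates and their within-imputation variances.

    Combined estimate is the mean; total variance is
    ``mean(within) + (1 + 1/M) * B`` with B the sample variance of the
    estimates; degrees of freedom follow the classical small-sample formula
    ``(M - 1) * (1 + W / ((1 + 1/M) B))^2`` (infinite when B = 0).
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(within_variances, dtype=float)
    m = q.size
    if m < 2 or w.size != m:
        raise ValueError("need M >= 2 estimates with matching within-variances")
    qbar = q.mean()
    b = q.var(ddof=1)
    wbar = w.mean()
    total = wbar + (1 + 1 / m) * b
    if b == 0:
        df = np.inf
    else:
        df = (m - 1) * (1 + wbar / ((1 + 1 / m) * b)) ** 2
    return RubinResult(estimate=float(qbar), total_variance=float(total),
                       within_variance=float(wbar), between_variance=float(b),
                       df=float(df), m=m)
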