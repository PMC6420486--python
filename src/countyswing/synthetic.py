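"""Synthetic county-panel generator.

Emulates the statistical structure the downstream analysis assumes, at desk
scale and with no external data:

* ~3,100 counties nested in 50 states, county populations heavy-right-skewed
  on the log10 scale, mapped to the 6 ordered urban-rural classes by
  population cutoffs;
* demographic/socioeconomic covariates at two time points whose 2000->2015
  changes drive the vote swing through known generating coefficients;
* a state-level bivariate-normal random intercept and random slope on the
  death-rate change, plus county residual noise, giving state clustering of
  the swing;
* all-cause death counts Poisson around a county-specific age-rate profile
  (11 age strata), so directly standardized rates reconstruct the latent
  county rate up to count noise;
* a rare "deaths of despair" stream (single aggregate stratum) with small
  Poisson counts, censored below the disclosure threshold — true values for
  censored cells go to a separate oracle table, never the public output.

The net Republican gain of each county equals the generating linear predictor
applied to the *realized* (count-based) death-rate change, so refitting the
model on the emitted tables recovers the generating coefficients without
errors-in-variables attenuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .rates import age_adjust, rate_deltas
from .standards import AGE_GROUPS, us2000_standard_million

logger = logging.getLogger(__name__)

#: age-specific all-cause death rates per 100,000 (US-like schedule); its
#: directly standardized rate under the US 2000 standard is ~773 per 100,000
#: and each county's profile is this schedule scaled to hit its target rate.
_AGE_RATE_PROFILE = np.array(
    [700.0, 30.0, 15.0, 80.0, 100.0, 200.0, 430.0, 900.0, 2000.0, 5000.0, 13500.0]
)


@dataclass
class SyntheticData:
    """Generator output: public tables plus hidden truth for oracle tests."""

    panel: pd.DataFrame
    deaths: pd.DataFrame
    oracle: pd.DataFrame          # true counts of suppressed cells (never published)
    state_effects: pd.DataFrame   # true (u_s, v_s) per state
    truth: dict = field(default_factory=dict)
    config: GeneratorConfig = None


def _counties_per_state(cfg: GeneratorConfig, rng) -> np.ndarray:
    w = rng.lognormal(0.0, 0.8, cfg.n_states)
    raw = w / w.sum() * cfg.n_counties_total
    counts = np.maximum(1, np.floor(raw).astype(int))
    # largest-remainder top-up to hit the exact total
    while counts.sum() < cfg.n_counties_total:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > cfg.n_counties_total:
        i = np.argmax(np.where(counts > 1, counts - raw, -np.inf))
        counts[i] -= 1
    return counts


def _urban_class(population: np.ndarray, thresholds) -> np.ndarray:
    # class 6 (noncore) below the first cutoff up to class 1 (large central metro)
    return 6 - np.searchsorted(np.asarray(thresholds), population, side="right")


def generate_panel(config: GeneratorConfig | None = None) -> SyntheticData:
    """Generate a county panel, death table and censoring oracle.

    Deterministic given ``config.seed``: regeneration is byte-identical.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    std = us2000_standard_million()
    w_age = std["weight"].to_numpy()

    per_state = _counties_per_state(cfg, rng)
    n = int(per_state.sum())
    state_ids = np.repeat([f"S{i + 1:02d}" for i in range(cfg.n_states)], per_state)
    county_ids = np.array([f"C{i + 1:04d}" for i in range(n)])

    population = np.maximum(
        cfg.population_min,
        np.round(10 ** rng.normal(cfg.population_log10_mean, cfg.population_log10_sd, n)),
    ).astype(int)
    urban = _urban_class(population, cfg.urban_thresholds)

    panel = pd.DataFrame({
        "county_id": county_ids, "state_id": state_ids,
        "population": population, "urban_rural": urban,
    })
    for c, (m0, s0, dm, ds) in cfg.covariate_params.items():
        lvl0 = rng.normal(m0, s0, n)
        chg = rng.normal(dm, ds, n)
        if c != "age" and c != "income":
            lvl0 = np.clip(lvl0, 0.0, 100.0)
            lvl1 = np.clip(lvl0 + chg, 0.0, 100.0)
        else:
            lvl0 = np.maximum(lvl0, 1.0)
            lvl1 = np.maximum(lvl0 + chg, 1.0)
        panel[f"{c}_2000"] = lvl0
        panel[f"{c}_2015"] = lvl1

    # --- all-cause mortality: latent target rates -> Poisson counts ---------
    rate00 = np.maximum(200.0, rng.normal(cfg.baseline_death_rate_mean,
                                          cfg.baseline_death_rate_sd, n))
    latent_delta = rng.normal(cfg.death_rate_change_mean, cfg.death_rate_change_sd, n)
    rate15 = np.maximum(100.0, rate00 + latent_delta)

    profile_adj = float(_AGE_RATE_PROFILE @ w_age)  # adjusted rate of the base schedule
    py_age = population[:, None] * w_age[None, :]   # person-years per age stratum
    death_rows = []
    for period, target in ((2000, rate00), (2015, rate15)):
        lam = (target / profile_adj)[:, None] * _AGE_RATE_PROFILE[None, :] * py_age / 1e5
        counts = rng.poisson(lam)
        death_rows.append(pd.DataFrame({
            "county_id": np.repeat(county_ids, len(AGE_GROUPS)),
            "state_id": np.repeat(state_ids, len(AGE_GROUPS)),
            "period": period,
            "cause_group": "all_cause",
            "age_group": np.tile(AGE_GROUPS, n),
            "count": counts.ravel().astype(float),
            "person_years": py_age.ravel(),
            "suppressed": False,
        }))
    allcause = pd.concat(death_rows, ignore_index=True)
    allcause_tot = (allcause.groupby(["county_id", "period"], sort=False)["count"]
                    .sum().unstack("period"))

    # --- rare-cause ("despair") stream with suppression ---------------------
    m_d, s_d, m_t, s_t = cfg.despair_rate_params
    drate00 = np.maximum(2.0, rng.normal(m_d, s_d, n))
    trend = rng.normal(m_t, s_t, n) + cfg.despair_link * (latent_delta
                                                          - cfg.death_rate_change_mean)
    drate15 = np.maximum(0.5, drate00 + trend)
    lo, hi = 1, cfg.suppression_threshold - 1
    despair_rows, other_rows, oracle_rows = [], [], []
    tot00 = allcause_tot[2000].reindex(county_ids).to_numpy()
    tot15 = allcause_tot[2015].reindex(county_ids).to_numpy()
    for period, drate, tot in ((2000, drate00, tot00), (2015, drate15, tot15)):
        dcount = np.minimum(rng.poisson(drate * population / 1e5), tot.astype(int))
        supp = (dcount >= lo) & (dcount <= hi)
        despair_rows.append(pd.DataFrame({
            "county_id": county_ids, "state_id": state_ids, "period": period,
            "cause_group": "despair", "age_group": "all",
            "count": np.where(supp, np.nan, dcount.astype(float)),
            "person_years": population.astype(float),
            "suppressed": supp,
        }))
        other_rows.append(pd.DataFrame({
            "county_id": county_ids, "state_id": state_ids, "period": period,
            "cause_group": "other", "age_group": "all",
            "count": np.where(supp, np.nan, (tot - dcount).astype(float)),
            "person_years": population.astype(float),
            "suppressed": supp,  # complement withheld too, else it reveals the count
        }))
        oracle_rows.append(pd.DataFrame({
            "county_id": county_ids[supp], "period": period,
            "cause_group": "despair", "true_count": dcount[supp],
        }))
    deaths = pd.concat([allcause, *despair_rows, *other_rows], ignore_index=True)
    oracle = pd.concat(oracle_rows, ignore_index=True)

    # --- realized adjusted rates drive the generated swing ------------------
    adj = age_adjust(allcause, std)
    realized = rate_deltas(adj).set_index("county_id")
    d_death = realized["delta"].reindex(county_ids).to_numpy()

    cov = cfg.rho_intercept_slope * cfg.sigma_state_intercept * cfg.sigma_state_slope
    G = np.array([[cfg.sigma_state_intercept**2, cov], [cov, cfg.sigma_state_slope**2]])
    uv = rng.multivariate_normal([0.0, 0.0], G, cfg.n_states)
    state_effects = pd.DataFrame(uv, columns=["u", "v"],
                                 index=[f"S{i + 1:02d}" for i in range(cfg.n_states)])
    u = np.repeat(uv[:, 0], per_state)
    v = np.repeat(uv[:, 1], per_state)
    eps = rng.normal(0.0, cfg.sigma_residual, n) if cfg.sigma_residual > 0 else np.zeros(n)

    tc = cfg.true_coefficients
    lp = np.log10(population)
    hinge = np.maximum(0.0, lp - np.log10(50_000))
    g = np.full(n, float(tc.get("intercept", 0.0)))
    for c in cfg.covariate_params:
        g += tc.get(c, 0.0) * (panel[f"{c}_2015"].to_numpy() - panel[f"{c}_2000"].to_numpy())
    g += (tc.get("death_rate", 0.0) + v) * d_death
    g += tc.get("rural", 0.0) * np.isin(urban, (5, 6)).astype(float)
    g += tc.get("log10_pop", 0.0) * lp
    g += (tc.get("log10_pop_above", 0.0) - tc.get("log10_pop", 0.0)) * hinge
    g += u + eps

    # --- vote shares and counts ---------------------------------------------
    r08 = np.clip(rng.normal(52.0, 10.0, n), 10.0, 80.0)
    other08 = rng.uniform(1.0, 4.0, n)
    d08 = 100.0 - r08 - other08
    # split of the swing: the Democratic share absorbs ~65% of it (third-party
    # growth takes the remainder). The split dd is bounded so all shares stay
    # inside [0.5, 99] with parties summing to <= 99.5; any feasible dd keeps
    # the net-gain identity exact since r16 - r08 = g + dd and d16 - d08 = dd.
    dd_raw = -0.65 * g + rng.normal(0.0, 2.0, n)
    dd_low = np.maximum(-(d08 - 0.5), 0.5 - r08 - g)
    dd_high = np.minimum.reduce([
        np.full(n, 40.0), 99.0 - d08, 99.0 - r08 - g, (99.5 - r08 - d08 - g) / 2.0])
    infeasible = dd_low > dd_high
    n_clip = int(infeasible.sum())
    if n_clip:
        logger.warning("generate_panel: %d counties had no feasible share split; their "
                       "shares are clipped and the net-gain identity breaks there", n_clip)
    dd = np.clip(dd_raw, dd_low, np.maximum(dd_low, dd_high))
    d16 = np.clip(d08 + dd, 0.5, 99.0)
    r16 = np.clip(r08 + g + dd, 0.5, np.minimum(99.0, 99.5 - d16))

    r00 = np.clip(r08 - rng.normal(1.5, 3.0, n), 0.5, 99.0)
    other00 = rng.uniform(1.0, 5.0, n)
    d00 = np.clip(100.0 - r00 - other00, 0.5, 99.0)

    panel["R00"], panel["D00"] = r00, d00
    panel["R08"], panel["D08"] = r08, d08
    panel["R16"], panel["D16"] = r16, d16

    total_votes = {}
    for yr, turnout_jitter in ((2008, rng.uniform(0.85, 1.15, n)),
                               (2016, rng.uniform(0.85, 1.15, n))):
        total_votes[yr] = np.round(population * cfg.turnout_fraction * turnout_jitter)
    panel["votes_total_2008"] = total_votes[2008].astype(int)
    panel["votes_total_2016"] = total_votes[2016].astype(int)
    panel["votes_rep_2008"] = np.round(r08 / 100 * total_votes[2008]).astype(int)
    panel["votes_dem_2008"] = np.round(d08 / 100 * total_votes[2008]).astype(int)
    panel["votes_rep_2016"] = np.round(r16 / 100 * total_votes[2016]).astype(int)
    panel["votes_dem_2016"] = np.round(d16 / 100 * total_votes[2016]).astype(int)

    truth = {
        "latent_rate_2000": rate00, "latent_delta": latent_delta,
        "realized_delta": d_death, "linear_predictor": g,
        "n_share_clipped": n_clip,
        "despair_rate_2000": drate00, "despair_rate_2015": drate15,
    }
    return SyntheticData(panel=panel, deaths=deaths, oracle=oracle,
                         state_effects=state_effects, truth=truth, config=cfg)


def write_outputs(data: SyntheticData, outdir) -> dict:
    """Write panel/deaths/oracle CSVs and a YAML echo of the config."""
    import dataclasses
    from pathlib import Path

    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.csv",
        "deaths": out / "deaths.csv",
        "oracle": out / "oracle.csv",
        "config": out / "generator_config.yaml",
    }
    data.panel.to_csv(paths["panel"], index=False)
    data.deaths.to_csv(paths["deaths"], index=False)
    data.oracle.to_csv(paths["oracle"], index=False)
    cfg = dataclasses.asdict(data.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
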