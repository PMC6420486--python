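"""Design-matrix construction for the multivariable voting-change model.

All demographic/socioeconomic covariates enter as 2000->2015 changes in their
natural units (years of median age, percentage points, thousands of dollars,
deaths per 100,000). Population enters as log10 with a hinge at 50,000 —
basis {log10(pop), max(0, log10(pop) - log10(50,000))} — so the piecewise
predictor is continuous at the knot and the below-knot slope is the first
coefficient while the above-knot slope is the sum of the two. Counties with
any missing covariate are dropped (complete-case analysis) and the exclusion
count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: socio-demographic covariates measured at both time points in the panel
COVARIATES = ("age", "black", "hispanic", "asian", "income",
              "unemployment", "bachelor", "insured")

POPULATION_KNOT = 50_000

#: urban-rural classes treated as rural (non-metro): micropolitan + noncore
RURAL_CLASSES = (5, 6)


@dataclass
class Design:
    """Model matrix, outcome, and grouping for the mixed model."""

    y: np.ndarray
    X: pd.DataFrame
    slope_covariate: np.ndarray       # death-rate change carrying the random slope
    groups: np.ndarray                # state ids
    county_ids: np.ndarray
    population: np.ndarray
    n_dropped: int
    outcome_name: str = "net_gain_2008_2016"
    slope_name: str = "d_death_rate"
    extra: dict = field(default_factory=dict)


def population_basis(population: np.ndarray, knot: float = POPULATION_KNOT):
    """Hinge basis for log10 population, continuous at the knot."""
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("population must be positive")
    lp = np.log10(population)
    return lp, np.maximum(0.0, lp - np.log10(knot))


def build_design(
    panel: pd.DataFrame,
    rate_deltas: pd.DataFrame,
    outcome: str = "2008_2016",
    cause_group: str = "all_cause",
) -> Design:
    """Assemble outcome and fixed-effect matrix from a county panel and rates.

    Parameters
    ----------
    panel
        County panel with vote shares, population, urban_rural class and
        ``{covariate}_2000`` / ``{covariate}_2015`` columns.
    rate_deltas
        Per-county adjusted-rate changes (columns ``county_id, cause_group,
        delta``), e.g. from :func:`countyswing.rates.rate_deltas`.
    outcome
        ``"2008_2016"`` (default) or ``"2000_2016"`` for the sensitivity
        analysis re-baselining the swing to the 2000 election.
    """
    rd = rate_deltas[rate_deltas["cause_group"] == cause_group]
    df = panel.merge(rd[["county_id", "delta"]].rename(columns={"delta": "d_death_rate"}),
                     on="county_id", how="left")

    if outcome == "2008_2016":
        y = (df["R16"] - df["R08"]) + (df["D08"] - df["D16"])
        outcome_name = "net_gain_2008_2016"
    elif outcome == "2000_2016":
        if "R00" not in df.columns:
            raise ValueError("panel lacks 2000 election shares (R00/D00)")
        y = (df["R16"] - df["R00"]) + (df["D00"] - df["D16"])
        outcome_name = "net_gain_2000_2016"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    df = df.assign(_y=y)

    cols = {}
    for c in COVARIATES:
        cols[f"d_{c}"] = df[f"{c}_2015"] - df[f"{c}_2000"]
    cols["d_death_rate"] = df["d_death_rate"]
    cols["rural"] = df["urban_rural"].isin(RURAL_CLASSES).astype(float)
    X = pd.DataFrame(cols)

    keep = X.notna().all(axis=1) & df["_y"].notna() & df["population"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: excluded %d counties with missing data (complete-case)",
                    n_dropped)
    df, X = df.loc[keep].reset_index(drop=True), X.loc[keep].reset_index(drop=True)

    lp, hinge = population_basis(df["population"].to_numpy())
    X.insert(0, "intercept", 1.0)
    X["log10_pop"] = lp
    X["log10_pop_hinge"] = hinge

    return Design(
        y=df["_y"].to_numpy(dtype=float),
        X=X,
        slope_covariate=X["d_death_rate"].to_numpy(),
        groups=df["state_id"].to_numpy(),
        county_ids=df["county_id"].to_numpy(),
        population=df["population"].to_numpy(dtype=float),
        n_dropped=n_dropped,
        outcome_name=outcome_name,
    )


def pca_design(design: Design, variance_fraction: float = 0.9) -> Design:
    """Replace the socio-demographic change covariates by principal components.

    The eight demographic/socioeconomic changes are standardized and rotated;
    components are retained (in order) until ``variance_fraction`` of their
    variance is explained (all of them at 1.0). The death-rate change,
    rural indicator and population basis are kept as-is.
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    change_cols = [f"d_{c}" for c in COVARIATES]
    Xc = design.X[change_cols].to_numpy()
    mu, sd = Xc.mean(axis=0), Xc.std(axis=0)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=len(change_cols), svd_solver="full")
    scores = pca.fit_transform((Xc - mu) / sd)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(max(k, 1), len(change_cols))

    X = design.X.drop(columns=change_cols).copy()
    for j in range(k):
        X[f"pc{j + 1}"] = scores[:, j]
    return Design(
        y=design.y, X=X, slope_covariate=design.slope_covariate,
        groups=design.groups, county_ids=design.county_ids,
        population=design.population, n_dropped=design.n_dropped,
        outcome_name=design.outcome_name,
        extra={"pca_components": k,
               "explained_variance_ratio": pca.explained_variance_ratio_[:k].tolist()},
    )


def despair_split_design(design: Design, despair_deltas: pd.DataFrame,
                         other_deltas: pd.DataFrame) -> Design:
    """Secondary model: split the death-rate change into despair vs other causes.

    The overall death-rate change column is replaced by two covariates
    (rare-cause "deaths of despair" change and all-other-cause change);
    the state random slope is carried by the dominant other-cause change.
    """
    ids = pd.DataFrame({"county_id": design.county_ids})
    dd = ids.merge(despair_deltas[["county_id", "delta"]], on="county_id", how="left")
    od = ids.merge(other_deltas[["county_id", "delta"]], on="county_id", how="left")
    X = design.X.drop(columns=["d_death_rate"]).copy()
    X["d_despair_rate"] = dd["delta"].to_numpy()
    X["d_other_rate"] = od["delta"].to_numpy()
    keep = X.notna().all(axis=1)
    n_extra = int((~keep).sum())
    if n_extra:
        logger.info("despair_split_design: %d further counties dropped (missing cause rates)",
                    n_extra)
    k = keep.to_numpy()
    return Design(
        y=design.y[k], X=X.loc[k].reset_index(drop=True),
        slope_covariate=X.loc[k, "d_other_rate"].to_numpy(),
        groups=design.groups[k], county_ids=design.county_ids[k],
        population=design.population[k],
        n_dropped=design.n_dropped + n_extra,
        outcome_name=design.outcome_name,
        slope_name="d_other_rate",
    )
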