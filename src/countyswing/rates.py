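"""Direct age standardization of county death rates.

A directly standardized ("age-adjusted") rate applies a county's
age-stratum-specific death rates to a fixed standard population:

    rate = 100,000 * sum_a w_a * (deaths_a / person_years_a),

with w_a the standard-population weights (summing to 1). This removes
age-structure differences between counties, so the adjusted rates are
comparable across counties and over time.

Death tables are long-format DataFrames with columns
``county_id, period, cause_group, age_group, count, person_years, suppressed``.
Cells flagged ``suppressed`` carry no count and must be imputed before
adjustment (all-cause tables are treated as fully observed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

DEATH_TABLE_COLUMNS = (
    "county_id", "period", "cause_group", "age_group", "count", "person_years", "suppressed",
)


def age_adjust(deaths: pd.DataFrame, std: pd.DataFrame) -> pd.DataFrame:
    """Directly standardized rate per 100,000 for each county/period/cause.

    Parameters
    ----------
    deaths
        Long-format death table (see module docstring); no suppressed cells.
        A single ``"all"`` age stratum is permitted (e.g. an aggregate
        rare-cause stream), in which case the "adjusted" rate is the crude
        rate regardless of ``std``.
    std
        Standard population with columns ``age_group, weight`` summing to 1.

    Returns
    -------
    DataFrame ``county_id, period, cause_group, rate`` (deaths per 100,000
    standard population).
    """
    if deaths["suppressed"].any():
        raise ValueError("age_adjust requires a completed table: suppressed cells present")
    d = deaths.copy()
    zero_py = d["person_years"] <= 0
    if zero_py.any():
        if (d.loc[zero_py, "count"] > 0).any():
            raise ValueError("zero person-years in a stratum with nonzero deaths")
        logger.warning("age_adjust: %d zero-person-year strata with zero deaths contribute 0",
                       int(zero_py.sum()))
        d = d.loc[~zero_py]

    single = d["age_group"].eq("all")
    out = []
    if single.any():
        crude = d.loc[single].copy()
        crude["rate"] = 1e5 * crude["count"] / crude["person_years"]
        out.append(crude[["county_id", "period", "cause_group", "rate"]])
    multi = d.loc[~single]
    if len(multi):
        w = std.set_index("age_group")["weight"]
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("standard population weights must sum to 1")
        unknown = set(multi["age_group"]) - set(w.index)
        if unknown:
            raise ValueError(f"age groups missing from standard population: {sorted(unknown)}")
        m = multi.assign(
            term=multi["age_group"].map(w).to_numpy()
            * multi["count"].to_numpy() / multi["person_years"].to_numpy()
        )
        adj = (
            m.groupby(["county_id", "period", "cause_group"], sort=True)["term"]
            .sum().mul(1e5).rename("rate").reset_index()
        )
        out.append(adj)
    res = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["county_id", "period", "cause_group", "rate"])
    return res.sort_values(["county_id", "period", "cause_group"]).reset_index(drop=True)


def rate_deltas(adjusted: pd.DataFrame, periods=(2000, 2015)) -> pd.DataFrame:
    """Per-county change in adjusted rate between two periods (later - earlier)."""
    wide = adjusted.pivot_table(index=["county_id", "cause_group"], columns="period",
                                values="rate", aggfunc="first")
    first, second = periods
    out = wide.reset_index()
    out["delta"] = out[second] - out[first]
    return out.rename(columns={first: f"rate_{first}", second: f"rate_{second}"})


def percent_difference(mean_a: float, mean_b: float, decimals: int | None = None) -> float:
    """100 * (mean_a - mean_b) / mean_b; rounded half-up when decimals given."""
    if mean_b == 0:
        raise ZeroDivisionError("reference group mean is zero")
    pct = 100.0 * (mean_a - mean_b) / mean_b
    return pct if decimals is None else round_half_up(pct, decimals)


def decline_percent(rate_2000: float, delta: float, decimals: int | None = None) -> float:
    """Magnitude of a 2000->2015 decline as a percent of the 2000 rate."""
    if rate_2000 == 0:
        raise ZeroDivisionError("baseline rate is zero")
    pct = 100.0 * abs(delta) / rate_2000
    return pct if decimals is None else round_half_up(pct, decimals)


def change_ratio(delta_a: float, delta_b: float, decimals: int | None = None) -> float:
    """Ratio of two rate changes (e.g. rare-cause increases between groups)."""
    if delta_b == 0:
        raise ZeroDivisionError("reference change is zero")
    r = delta_a / delta_b
    return r if decimals is None else round_half_up(r, decimals)


def rate_contrasts(group_a: pd.DataFrame, group_b: pd.DataFrame,
                   cause_group: str = "all_cause") -> dict:
    """Group-level rate contrasts between two collections of adjusted rates.

    Each input holds per-county ``rate_2000, rate_2015, delta`` rows (output of
    :func:`rate_deltas`) for one comparison group. Returns the contrasts the
    analysis reports: the later-period percent difference A vs B, each group's
    percent decline since baseline, and the ratio of the groups' changes.
    """
    a = group_a[group_a["cause_group"] == cause_group]
    b = group_b[group_b["cause_group"] == cause_group]
    if a.empty or b.empty:
        raise ValueError(f"no rows for cause_group={cause_group!r}")
    ma15, mb15 = a["rate_2015"].mean(), b["rate_2015"].mean()
    ma00, mb00 = a["rate_2000"].mean(), b["rate_2000"].mean()
    da, db = a["delta"].mean(), b["delta"].mean()
    return {
        "pct_diff_2015": percent_difference(ma15, mb15),
        "decline_pct_a": decline_percent(ma00, da),
        "decline_pct_b": decline_percent(mb00, db),
        "change_ratio": change_ratio(da, db) if db != 0 else np.nan,
        "means": {"a_2000": ma00, "a_2015": ma15, "b_2000": mb00, "b_2015": mb15,
                  "a_delta": da, "b_delta": db},
    }
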