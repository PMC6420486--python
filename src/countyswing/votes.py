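"""Vote-swing outcome and county classifications.

The outcome of the analysis is the *net Republican percentage gain*: the signed
sum, in percentage points, of the change in the Republican share plus the
negative of the change in the Democratic share between two presidential
elections,

    g = (R16 - R08) + (D08 - D16).

A county whose Republican share fell can still show a positive net gain when
the Democratic share fell by more; the statistic is signed, never truncated
at zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

GAIN_LABELS = ("republican_gain", "democratic_gain", "both_decline", "both_gain")

_SHARE_COLS = ("R08", "D08", "R16", "D16")


def _check_shares(df: pd.DataFrame, cols=_SHARE_COLS) -> None:
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        bad = (v < 0) | (v > 100)
        if np.any(bad & ~np.isnan(v)):
            raise ValueError(f"vote share column {c} outside [0, 100]")


def net_republican_gain(panel: pd.DataFrame) -> pd.DataFrame:
    """Compute the signed net Republican gain per county.

    Parameters
    ----------
    panel
        One row per county with percentage-point share columns
        ``R08, D08, R16, D16`` and a ``county_id`` column.

    Returns
    -------
    DataFrame with columns ``county_id, net_gain`` (percentage points,
    may be negative).
    """
    _check_shares(panel)
    g = (panel["R16"] - panel["R08"]) + (panel["D08"] - panel["D16"])
    return pd.DataFrame({"county_id": panel["county_id"], "net_gain": g.astype(float)})


def classify_counties(panel: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Label each county by which party improved its share in 2016 vs 2008.

    Labels: ``republican_gain`` (R16 > R08 only), ``democratic_gain``
    (D16 > D08 only), ``both_gain`` (both improved), ``both_decline``
    (neither improved). Counties with a missing share are excluded and logged,
    mirroring complete-case handling.

    Returns
    -------
    (labels, counts)
        ``labels``: DataFrame ``county_id, label``. ``counts``: Series over
        the four labels plus marginal counts ``republican_marginal`` /
        ``democratic_marginal`` that include ``both_gain`` counties in each
        party's total (the convention in which the marginals over-count the
        both-gain counties once).
    """
    complete = panel.dropna(subset=list(_SHARE_COLS))
    n_dropped = len(panel) - len(complete)
    if n_dropped:
        logger.warning("classify_counties: excluded %d counties with missing shares", n_dropped)
    _check_shares(complete)

    r_up = complete["R16"].to_numpy() > complete["R08"].to_numpy()
    d_up = complete["D16"].to_numpy() > complete["D08"].to_numpy()
    double_tie = (complete["R16"].to_numpy() == complete["R08"].to_numpy()) & (
        complete["D16"].to_numpy() == complete["D08"].to_numpy()
    )
    if double_tie.any():
        logger.warning("classify_counties: %d exact double-tie counties fall in both_decline",
                       int(double_tie.sum()))

    label = np.where(
        r_up & d_up, "both_gain",
        np.where(r_up, "republican_gain",
                 np.where(d_up, "democratic_gain", "both_decline")),
    )
    labels = pd.DataFrame({"county_id": complete["county_id"], "label": label})
    counts = labels["label"].value_counts().reindex(GAIN_LABELS, fill_value=0)
    counts["republican_marginal"] = counts["republican_gain"] + counts["both_gain"]
    counts["democratic_marginal"] = counts["democratic_gain"] + counts["both_gain"]
    return labels, counts


def category_percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of counties in a category, rounded half-up for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, decimals)


def vote_totals_delta(totals: pd.DataFrame) -> pd.DataFrame:
    """Candidate vote totals in millions and their change across elections.

    Parameters
    ----------
    totals
        Columns ``party, election, votes`` (non-negative counts; ``votes`` may
        already be in millions — values below 1,000 are taken as millions).

    Returns
    -------
    One row per party with ``votes_millions`` per election (one decimal) and
    ``delta_millions`` = later minus earlier election, signed.
    """
    if (totals["votes"] < 0).any():
        raise ValueError("vote counts must be non-negative")
    t = totals.copy()
    t["millions"] = np.where(t["votes"] >= 1000, t["votes"] / 1e6, t["votes"])
    wide = t.pivot(index="party", columns="election", values="millions")
    elections = sorted(wide.columns)
    if len(elections) != 2:
        raise ValueError("expected exactly two elections")
    first, second = elections
    out = pd.DataFrame({
        "party": wide.index,
        f"votes_{first}_millions": round_half_up(wide[first].to_numpy(), 1),
        f"votes_{second}_millions": round_half_up(wide[second].to_numpy(), 1),
        "delta_millions": round_half_up((wide[second] - wide[first]).to_numpy(), 1),
    }).reset_index(drop=True)
    return out
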