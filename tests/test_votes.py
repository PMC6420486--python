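"""Net-gain arithmetic, county classification and vote-total deltas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countyswing.votes import (category_percentage, classify_counties,
                               net_republican_gain, vote_totals_delta)


def _panel(rows):
    return pd.DataFrame(rows, columns=["county_id", "R08", "D08", "R16", "D16"])


@pytest.mark.parametrize(
    "r08,d08,r16,d16,expected",
    [
        # Republican share fell, yet the net gain is positive because the
        # Democratic share fell by more
        (40, 55, 38, 50, 3.0),
        (50, 45, 50, 45, 0.0),
        (50, 45, 45, 50, -10.0),
    ],
)
def test_net_gain_signed_sum(r08, d08, r16, d16, expected):
    out = net_republican_gain(_panel([("c1", r08, d08, r16, d16)]))
    assert out["net_gain"].iloc[0] == pytest.approx(expected)


def test_net_gain_rejects_out_of_range_shares():
    with pytest.raises(ValueError, match="outside"):
        net_republican_gain(_panel([("c1", 101.0, 10, 50, 40)]))


@settings(max_examples=200, deadline=None)
@given(st.tuples(*[st.floats(0, 100) for _ in range(4)]))
def test_net_gain_swap_symmetries(shares):
    """Swapping the parties flips the sign of g; so does reversing the two
    elections; doing both restores it."""
    r08, d08, r16, d16 = shares

    def g(a, b, c, d):
        return net_republican_gain(_panel([("c", a, b, c, d)]))["net_gain"].iloc[0]

    base = g(r08, d08, r16, d16)
    assert g(d08, r08, d16, r16) == pytest.approx(-base, abs=1e-9)  # party swap
    assert g(r16, d16, r08, d08) == pytest.approx(-base, abs=1e-9)  # year swap
    assert g(d16, r16, d08, r08) == pytest.approx(base, abs=1e-9)   # both


def test_classify_counties_one_per_category():
    panel = _panel([
        ("rep", 40, 50, 45, 48),    # R up, D down
        ("dem", 40, 50, 38, 55),    # R down, D up
        ("decl", 40, 50, 38, 48),   # both down
        ("both", 40, 50, 45, 55),   # both up
    ])
    labels, counts = classify_counties(panel)
    assert set(labels["label"]) == {"republican_gain", "democratic_gain",
                                    "both_decline", "both_gain"}
    assert all(counts[k] == 1 for k in
               ("republican_gain", "democratic_gain", "both_decline", "both_gain"))
    # marginal counts include the both-gain county on each side
    assert counts["republican_marginal"] == 2
    assert counts["democratic_marginal"] == 2


def test_classify_counties_drops_and_logs_missing(caplog):
    panel = _panel([("a", 40, 50, 45, 48), ("b", np.nan, 50, 38, 55)])
    with caplog.at_level("WARNING"):
        labels, counts = classify_counties(panel)
    assert len(labels) == 1
    assert counts.iloc[:4].sum() == 1


def test_classification_invariant_to_constant_party_shift():
    base = _panel([("a", 40, 50, 45, 48), ("b", 40, 50, 38, 55)])
    shifted = base.copy()
    shifted[["R08", "R16"]] += 5.0  # same constant in both elections
    l0, _ = classify_counties(base)
    l1, _ = classify_counties(shifted)
    assert (l0["label"] == l1["label"]).all()


@pytest.mark.parametrize("count,total,expected", [
    (2607, 3112, 83.8),
    (108, 3112, 3.5),
    (398, 3112, 12.8),
])
def test_category_percentage_printed_precision(count, total, expected):
    assert category_percentage(count, total) == pytest.approx(expected)


def test_vote_totals_delta_millions():
    totals = pd.DataFrame({
        "party": ["dem", "dem", "rep", "rep"],
        "election": [2008, 2016, 2008, 2016],
        "votes": [69.5e6, 65.9e6, 60.0e6, 63.0e6],
    })
    out = vote_totals_delta(totals).set_index("party")
    assert out.loc["dem", "delta_millions"] == pytest.approx(-3.6)
    assert out.loc["rep", "delta_millions"] == pytest.approx(3.0)


def test_vote_totals_delta_equal_totals_is_zero():
    totals = pd.DataFrame({"party": ["x", "x"], "election": [2008, 2016],
                           "votes": [1_000_000, 1_000_000]})
    assert vote_totals_delta(totals)["delta_millions"].iloc[0] == 0.0
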