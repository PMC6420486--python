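"""Direct age standardization and the group rate contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countyswing.rates import (age_adjust, change_ratio, decline_percent,
                               percent_difference, rate_contrasts, rate_deltas)


def _table(counts, py, age_groups=None, county="c1", period=2015, cause="all_cause"):
    age_groups = age_groups or [f"a{i}" for i in range(len(counts))]
    return pd.DataFrame({
        "county_id": county, "period": period, "cause_group": cause,
        "age_group": age_groups, "count": np.asarray(counts, dtype=float),
        "person_years": np.asarray(py, dtype=float), "suppressed": False,
    })


def _std(weights, age_groups=None):
    age_groups = age_groups or [f"a{i}" for i in range(len(weights))]
    return pd.DataFrame({"age_group": age_groups, "weight": weights})


def test_two_strata_forced_arithmetic():
    # rates (0.001, 0.002) with equal weights -> 150 per 100,000
    t = _table([10, 20], [10_000, 10_000])
    out = age_adjust(t, _std([0.5, 0.5]))
    assert out["rate"].iloc[0] == pytest.approx(150.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
       st.floats(1e-5, 0.01))
def test_standardization_identity_uniform_rates(raw_w, r):
    """Identical stratum rates r give adjusted rate 100,000*r for any weights."""
    w = np.asarray(raw_w) / np.sum(raw_w)
    py = np.full(len(w), 50_000.0)
    t = _table(r * py, py)
    out = age_adjust(t, _std(list(w)))
    assert out["rate"].iloc[0] == pytest.approx(1e5 * r, rel=1e-9)


def test_matches_bruteforce_oracle():
    """Randomized tables must agree with an explicit per-stratum summation."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        k = rng.integers(2, 8)
        counts = rng.integers(0, 400, k)
        py = rng.uniform(1e3, 1e6, k)
        w = rng.dirichlet(np.ones(k))
        expected = 1e5 * sum(w[i] * counts[i] / py[i] for i in range(k))
        out = age_adjust(_table(counts, py), _std(list(w)))
        assert out["rate"].iloc[0] == pytest.approx(expected, rel=1e-12)


def test_linear_in_counts_and_bounded_by_stratum_rates():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 300, 5)
    py = rng.uniform(1e4, 1e5, 5)
    w = rng.dirichlet(np.ones(5))
    r1 = age_adjust(_table(counts, py), _std(list(w)))["rate"].iloc[0]
    r2 = age_adjust(_table(2 * counts, py), _std(list(w)))["rate"].iloc[0]
    assert r2 == pytest.approx(2 * r1, rel=1e-12)
    stratum = 1e5 * counts / py
    assert stratum.min() - 1e-9 <= r1 <= stratum.max() + 1e-9


def test_zero_person_years_with_deaths_is_an_error():
    t = _table([5, 1], [10_000, 0])
    with pytest.raises(ValueError, match="person-years"):
        age_adjust(t, _std([0.5, 0.5]))


def test_zero_person_years_without_deaths_contributes_zero(caplog):
    t = _table([5, 0], [10_000, 0])
    with caplog.at_level("WARNING"):
        out = age_adjust(t, _std([0.5, 0.5]))
    assert out["rate"].iloc[0] == pytest.approx(1e5 * 0.5 * 5 / 10_000)


def test_suppressed_cells_are_rejected():
    t = _table([5, 3], [1e4, 1e4])
    t.loc[0, "suppressed"] = True
    with pytest.raises(ValueError, match="suppressed"):
        age_adjust(t, _std([0.5, 0.5]))


@pytest.mark.parametrize("a,b,decimals,expected", [
    (848.2, 734.6, 0, 15.0),   # later-period contrast, integer style
    (838.8, 781.2, 1, 7.4),    # won-county contrast, one-decimal style
])
def test_percent_difference_printed_values(a, b, decimals, expected):
    assert percent_difference(a, b, decimals) == pytest.approx(expected)


def test_decline_percent_and_change_ratio_printed_values():
    assert decline_percent(922.1, -73.9, 0) == pytest.approx(8.0)
    assert decline_percent(895.0, -160.4, 0) == pytest.approx(18.0)
    assert change_ratio(21.9, 8.8, 1) == pytest.approx(2.5)


def test_rate_contrast_of_group_with_itself_is_zero():
    df = pd.DataFrame({"county_id": ["a", "b"], "cause_group": "all_cause",
                       "rate_2000": [900.0, 800.0], "rate_2015": [850.0, 760.0],
                       "delta": [-50.0, -40.0]})
    out = rate_contrasts(df, df)
    assert out["pct_diff_2015"] == pytest.approx(0.0)
    assert out["change_ratio"] == pytest.approx(1.0)


def test_rate_deltas_is_later_minus_earlier():
    adj = pd.DataFrame({
        "county_id": ["c", "c"], "period": [2000, 2015],
        "cause_group": "all_cause", "rate": [900.0, 820.0]})
    out = rate_deltas(adj)
    assert out["delta"].iloc[0] == pytest.approx(-80.0)
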