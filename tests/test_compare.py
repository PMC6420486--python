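"""State-clustered group comparisons and the two-election interaction model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from countyswing.compare import (compare_groups, election_interaction_model,
                                 naive_compare)


def _null_data(rng, n_states=20, per_state=6, sigma_state=0.0):
    u = rng.normal(0, sigma_state, n_states)
    y = np.repeat(u, per_state) + rng.normal(0, 1, n_states * per_state)
    g = np.where(rng.random(n_states * per_state) < 0.5, "a", "b")
    st_ids = np.repeat([f"S{i}" for i in range(n_states)], per_state)
    return y, g, st_ids


def test_identical_values_give_zero_difference_and_p_one():
    y = np.ones(40)
    g = np.array(["a", "b"] * 20)
    st_ids = np.repeat([f"S{i}" for i in range(8)], 5)
    res = compare_groups(y, g, st_ids)
    assert res.difference == 0.0
    assert res.pvalue == pytest.approx(1.0)


def test_matches_unclustered_test_when_no_state_variance():
    """With zero between-state variance the clustered test collapses to an
    ordinary pooled two-sample z-test."""
    rng = np.random.default_rng(8)
    y, g, st_ids = _null_data(rng, sigma_state=0.0)
    # remove all between-state signal so the variance estimate hits its zero
    # boundary and the model collapses to ordinary least squares
    y = y - pd.Series(y).groupby(pd.Series(st_ids)).transform("mean").to_numpy()
    res = compare_groups(y, g, st_ids)
    # pooled-variance z oracle on the same data
    ya, yb = y[g == "a"], y[g == "b"]
    sp2 = (((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()) / (len(y) - 2)
    se = np.sqrt(sp2 * (1 / len(ya) + 1 / len(yb)))
    z = (ya.mean() - yb.mean()) / se
    p = 2 * stats.norm.sf(abs(z))
    assert res.pvalue == pytest.approx(p, abs=1e-6)
    assert res.difference == pytest.approx(ya.mean() - yb.mean(), abs=1e-6)


def test_invariant_to_state_relabeling_and_location_shift():
    rng = np.random.default_rng(4)
    y, g, st_ids = _null_data(rng, sigma_state=1.0)
    res = compare_groups(y, g, st_ids)
    perm = {f"S{i}": f"T{(i * 7) % 20}" for i in range(20)}
    res_relabel = compare_groups(y, g, np.vectorize(perm.get)(st_ids))
    assert res_relabel.difference == pytest.approx(res.difference, rel=1e-6)
    assert res_relabel.pvalue == pytest.approx(res.pvalue, rel=1e-4)
    res_shift = compare_groups(y + 100.0, g, st_ids)
    assert res_shift.difference == pytest.approx(res.difference, abs=1e-6)
    assert res_shift.pvalue == pytest.approx(res.pvalue, rel=1e-4)


def test_single_state_group_warns(caplog):
    y = np.r_[np.ones(5) + 0.1 * np.arange(5), np.zeros(10) + 0.05 * np.arange(10)]
    g = np.array(["a"] * 5 + ["b"] * 10)
    st_ids = np.array(["S1"] * 5 + ["S2"] * 5 + ["S3"] * 5)
    with caplog.at_level("WARNING"):
        compare_groups(y, g, st_ids)
    assert any("one state" in r.message for r in caplog.records)


def test_requires_two_groups_and_two_states():
    with pytest.raises(ValueError, match="2 groups"):
        compare_groups([1.0, 2.0], ["a", "a"], ["S1", "S2"])
    with pytest.raises(ValueError, match="2 states"):
        compare_groups([1.0, 2.0], ["a", "b"], ["S1", "S1"])


def _interaction_frame(rng, delta, n_states=20, per_state=8):
    n = n_states * per_state
    u = rng.normal(0, 1, n_states)
    cty = rng.normal(0, 1, n)
    grp = rng.random(n) < 0.5
    frames = []
    for e, yr in enumerate((2008, 2016)):
        y = (np.repeat(u, per_state) + cty + 0.5 * grp + delta * e * grp
             + rng.normal(0, 0.5, n))
        frames.append(pd.DataFrame({
            "county_id": [f"C{i}" for i in range(n)],
            "state_id": np.repeat([f"S{i}" for i in range(n_states)], per_state),
            "election": yr, "group": np.where(grp, "a", "b"), "value": y}))
    return pd.concat(frames, ignore_index=True)


def test_interaction_zero_when_gap_is_stable():
    rng = np.random.default_rng(17)
    df = _interaction_frame(rng, delta=0.0)
    res = election_interaction_model(df)
    assert abs(res.difference) < 3 * res.se
    assert res.model == "3-level interaction"


def test_interaction_recovers_known_widening():
    """A gap widening of delta=1.5 should be recovered within 3 SE in at
    least 19 of 20 seeded replicates."""
    delta = 1.5
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        res = election_interaction_model(_interaction_frame(rng, delta))
        hits += abs(res.difference - delta) <= 3 * res.se
    assert hits >= 19


def test_interaction_drops_one_election_counties(caplog):
    rng = np.random.default_rng(2)
    df = _interaction_frame(rng, delta=0.0)
    df = df.drop(df[(df["county_id"] == "C0") & (df["election"] == 2016)].index)
    with caplog.at_level("INFO"):
        res = election_interaction_model(df)
    assert res.ns[0] + res.ns[1] == df["county_id"].nunique() - 1


def test_naive_test_returns_welch_p():
    rng = np.random.default_rng(0)
    y, g, _ = _null_data(rng)
    t, p = naive_compare(y, g)
    t2, p2 = stats.ttest_ind(y[g == "a"], y[g == "b"], equal_var=False)
    assert (t, p) == (pytest.approx(t2), pytest.approx(p2))
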