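"""Interval-censored Poisson imputation: support, determinism, shrinkage."""

import numpy as np
import pandas as pd
import pytest

from countyswing.config import CensoringRule, ImputationModelSpec
from countyswing.imputation import (ImputationConvergenceError,
                                    fit_imputation_model)
from countyswing.rates import age_adjust, rate_deltas
from countyswing.standards import us2000_standard_million

FAST = ImputationModelSpec(chains=2, warmup=300, draws=300, m_datasets=5, seed=3,
                           rhat_threshold=1.5)


def _despair(data):
    return data.deaths[data.deaths["cause_group"] == "despair"]


def test_imputed_values_respect_the_censoring_interval(small_data):
    imp = fit_imputation_model(_despair(small_data), CensoringRule(), FAST)
    assert imp.imputed_counts.min() >= 1
    assert imp.imputed_counts.max() <= 9
    # observed cells identical across all completed datasets
    obs_mask = ~imp.base["suppressed"].to_numpy()
    first = imp.dataset(0)["count"].to_numpy()[obs_mask]
    for m in range(1, imp.m):
        assert np.array_equal(imp.dataset(m)["count"].to_numpy()[obs_mask], first)


def test_no_censored_cells_returns_identical_copies(small_data):
    t = _despair(small_data).copy()
    t.loc[t["suppressed"], "count"] = 5.0  # pre-completed table, nothing censored
    t["suppressed"] = False
    imp = fit_imputation_model(t, CensoringRule(), FAST)
    assert imp.diagnostics["n_censored"] == 0
    sets = list(imp.datasets())
    assert len(sets) == FAST.m_datasets
    for s in sets:
        pd.testing.assert_frame_equal(
            s.drop(columns="suppressed"),
            t.reset_index(drop=True).drop(columns="suppressed"))


def test_seed_reproducibility(small_data):
    a = fit_imputation_model(_despair(small_data), CensoringRule(), FAST)
    b = fit_imputation_model(_despair(small_data), CensoringRule(), FAST)
    assert np.array_equal(a.imputed_counts, b.imputed_counts)


def test_imputation_beats_midpoint_fill(small_data):
    """Posterior means should track hidden truth better than filling 5s."""
    spec = ImputationModelSpec(chains=4, warmup=500, draws=500, m_datasets=10,
                               seed=9, rhat_threshold=1.3)
    imp = fit_imputation_model(_despair(small_data), CensoringRule(), spec)
    truth = small_data.oracle.set_index(["county_id", "period"])["true_count"]
    j = imp.summaries.set_index(["county_id", "period"]).join(truth)
    mae = np.abs(j["post_mean"] - j["true_count"]).mean()
    mae_midpoint = np.abs(5.0 - j["true_count"]).mean()
    assert mae < mae_midpoint


def test_small_county_rate_shrinks_toward_state_mean():
    """A tiny censored county's imputed rate lies between its interval
    midpoint and the state rate set by a large observed county."""
    state_rate = 100.0 / 1e5
    py_big, py_small = 2_000_000.0, 3_000.0
    rows = []
    for period in (2000, 2015):
        rows.append(("big", "S1", period, round(state_rate * py_big), py_big, False))
        rows.append(("small", "S1", period, np.nan, py_small, True))
    t = pd.DataFrame(rows, columns=["county_id", "state_id", "period", "count",
                                    "person_years", "suppressed"])
    spec = ImputationModelSpec(chains=4, warmup=800, draws=800, m_datasets=10,
                               seed=21, rhat_threshold=1.5)
    imp = fit_imputation_model(t, CensoringRule(), spec)
    rate_small = 1e5 * imp.summaries["post_mean"].mean() / py_small
    midpoint_rate = 1e5 * 5.0 / py_small
    assert (1e5 * state_rate) < rate_small < midpoint_rate


def test_pipeline_equivariance_of_rates_and_combining(small_data):
    """Mean of per-dataset adjusted rates equals the rate of the mean counts
    (direct standardization is linear in counts)."""
    imp = fit_imputation_model(_despair(small_data), CensoringRule(), FAST)
    std = us2000_standard_million()
    per_dataset = [age_adjust(d, std)["rate"].to_numpy() for d in imp.datasets()]
    combined_rates = np.mean(per_dataset, axis=0)

    mean_counts = imp.dataset(0).copy()
    stacked = np.stack([d["count"].to_numpy() for d in imp.datasets()])
    mean_counts["count"] = stacked.mean(axis=0)
    rate_of_mean = age_adjust(mean_counts, std)["rate"].to_numpy()
    np.testing.assert_allclose(combined_rates, rate_of_mean, atol=1e-9)


def test_nonconvergence_raises_with_diagnostics(small_data):
    spec = ImputationModelSpec(chains=2, warmup=5, draws=20, m_datasets=2,
                               seed=1, rhat_threshold=1.0001)
    with pytest.raises(ImputationConvergenceError) as exc:
        fit_imputation_model(_despair(small_data), CensoringRule(), spec)
    assert "rhat" in exc.value.diagnostics


def test_censoring_rule_validation():
    with pytest.raises(ValueError):
        CensoringRule(threshold=1, lower=1)
    with pytest.raises(ValueError):
        CensoringRule(threshold=10, lower=3)
    assert CensoringRule().interval == (1, 9)
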