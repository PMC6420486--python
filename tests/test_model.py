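"""Design construction, the multivariable fit, and the sensitivity suite."""

import numpy as np
import pandas as pd
import pytest

from countyswing.config import DEFAULT_TRUE_COEFFICIENTS, GeneratorConfig
from countyswing.design import (POPULATION_KNOT, build_design, pca_design,
                                population_basis)
from countyswing.model import fit_primary, sensitivity_suite
from countyswing.rates import age_adjust, rate_deltas
from countyswing.standards import us2000_standard_million
from countyswing.synthetic import generate_panel


def test_piecewise_basis_continuous_at_knot():
    eps = 1e-9
    lp, hinge = population_basis(np.array([POPULATION_KNOT * (1 - eps),
                                           POPULATION_KNOT,
                                           POPULATION_KNOT * (1 + eps)]))
    b_below, b_above = -2.97, -7.21
    pred = b_below * lp + (b_above - b_below) * hinge
    assert pred[0] == pytest.approx(pred[1], abs=1e-6)
    assert pred[2] == pytest.approx(pred[1], abs=1e-6)
    assert hinge[1] == 0.0


def test_tenfold_population_increase_below_knot():
    lp, hinge = population_basis(np.array([1_000.0, 10_000.0]))
    assert lp[1] - lp[0] == pytest.approx(1.0)
    assert hinge[0] == hinge[1] == 0.0


def test_nonpositive_population_rejected():
    with pytest.raises(ValueError):
        population_basis(np.array([0.0]))


def test_missing_covariate_counties_are_excluded(mid_data, mid_rate_deltas, caplog):
    panel = mid_data.panel.copy()
    panel.loc[panel.index[:7], "income_2015"] = np.nan
    with caplog.at_level("INFO"):
        design = build_design(panel, mid_rate_deltas)
    assert design.n_dropped == 7
    assert len(design.y) == len(panel) - 7


def test_noise_free_generator_gives_exact_linear_predictor_and_r2_one():
    cfg = GeneratorConfig(seed=2, n_states=15, n_counties_total=150,
                          sigma_state_intercept=0.0, sigma_state_slope=0.0,
                          rho_intercept_slope=0.0, sigma_residual=0.0)
    data = generate_panel(cfg)
    g = (data.panel["R16"] - data.panel["R08"]) + (data.panel["D08"] - data.panel["D16"])
    np.testing.assert_allclose(g, data.truth["linear_predictor"], atol=1e-9)

    std = us2000_standard_million()
    rd = rate_deltas(age_adjust(
        data.deaths[data.deaths["cause_group"] == "all_cause"], std))
    fit = fit_primary(build_design(data.panel, rd))
    assert fit.r2_total == pytest.approx(1.0, abs=1e-6)


def test_zero_coefficients_and_zero_variance_give_constant_gain():
    tc = {k: 0.0 for k in DEFAULT_TRUE_COEFFICIENTS}
    tc["intercept"] = 12.5
    cfg = GeneratorConfig(seed=3, n_states=5, n_counties_total=30,
                          true_coefficients=tc, sigma_state_intercept=0.0,
                          sigma_state_slope=0.0, rho_intercept_slope=0.0,
                          sigma_residual=0.0)
    data = generate_panel(cfg)
    g = (data.panel["R16"] - data.panel["R08"]) + (data.panel["D08"] - data.panel["D16"])
    np.testing.assert_allclose(g, 12.5, atol=1e-9)


def test_reciprocal_presentation_is_consistent(mid_design):
    fit = fit_primary(mid_design)
    for name, mag in fit.magnitude_per_1pct.items():
        assert mag * fit.coef[name] == pytest.approx(1.0, abs=1e-12)
    assert fit.population_slopes["above_knot_per_10fold"] == pytest.approx(
        fit.coef["log10_pop"] + fit.coef["log10_pop_hinge"])


def test_scaling_slope_covariate_rescales_coefficient(mid_design):
    fit0 = fit_primary(mid_design)
    import copy

    design2 = copy.copy(mid_design)
    design2.X = mid_design.X.copy()
    design2.X["d_death_rate"] = design2.X["d_death_rate"] / 100.0
    design2.slope_covariate = design2.X["d_death_rate"].to_numpy()
    fit2 = fit_primary(design2)
    assert fit2.coef["d_death_rate"] == pytest.approx(
        100.0 * fit0.coef["d_death_rate"], rel=1e-4)
    np.testing.assert_allclose(
        fit2.coef.drop(["d_death_rate"]).to_numpy(),
        fit0.coef.drop(["d_death_rate"]).to_numpy(), rtol=1e-4, atol=1e-6)


def test_pca_full_rank_reproduces_primary_fit(mid_design):
    fit0 = fit_primary(mid_design)
    fitp = fit_primary(pca_design(mid_design, variance_fraction=1.0))
    assert fitp.extra["pca_components"] == 8
    assert fitp.coef["d_death_rate"] == pytest.approx(
        fit0.coef["d_death_rate"], abs=1e-6)
    assert fitp.r2_fixed == pytest.approx(fit0.r2_fixed, abs=1e-6)


def test_sensitivity_suite_death_slopes_agree(mid_data, mid_rate_deltas):
    fits = sensitivity_suite(mid_data.panel, mid_rate_deltas)
    assert set(fits) == {"primary", "weighted", "pca", "baseline2000"}
    slopes = {k: f.coef["d_death_rate"] for k, f in fits.items()}
    assert all(s > 0 for s in slopes.values())
    # all four within 2 SE of the primary estimate (stability across analyses)
    se0 = fits["primary"].se["d_death_rate"]
    for k, s in slopes.items():
        assert abs(s - slopes["primary"]) <= 2 * (se0 + fits[k].se["d_death_rate"])


def test_r2_ordering_and_state_slopes(mid_design):
    fit = fit_primary(mid_design)
    assert 0 <= fit.r2_fixed <= fit.r2_total <= 1
    assert len(fit.state_slopes) == len(np.unique(mid_design.groups))
    # total slopes scatter around the fixed coefficient
    assert fit.state_slopes.mean() == pytest.approx(
        fit.coef["d_death_rate"], abs=5 * np.sqrt(max(fit.sigma_v2, 1e-12)))
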