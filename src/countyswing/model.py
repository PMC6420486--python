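"""The multivariable random-slope model for net Republican gain.

Fixed effects: changes in median age, % Black, % Hispanic, % Asian/PI,
median income ($1000s), unemployment %, % bachelor's+, % insured, and the
age-adjusted death-rate change (per 100,000), plus a rural indicator and a
piecewise log10(population) term with a knot at 50,000. Random effects: a
state intercept and a state slope on the death-rate change, bivariate normal
with free correlation. Estimated by maximum likelihood (see
:mod:`countyswing.lmm`).

Reported alongside the coefficients:

* the *reciprocal presentation* — the magnitude of each covariate change
  associated with one percentage point of net gain (1/coefficient), which is
  how such models are often tabulated;
* an R^2 decomposition — variance of the fixed-effect predictions over
  variance of the outcome, and the same with random-effect predictions added
  (the variance-of-predictions convention);
* per-state total death-rate slopes (fixed coefficient + predicted random
  slope), the input to the electoral counterfactual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design, build_design, despair_split_design, pca_design
from .lmm import LMMResult, fit_lmm


@dataclass
class ModelFit:
    """Summary of one multivariable mixed-model fit."""

    model: str
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma_u2: float
    sigma_v2: float
    rho: float
    sigma_e2: float
    r2_fixed: float
    r2_total: float
    #: per-state total slope on the death-rate change (points per unit per 100,000)
    state_slopes: pd.Series
    #: 1/coef for the change covariates: magnitude per 1 point of net gain
    magnitude_per_1pct: pd.Series
    loglik: float
    n_obs: int
    n_dropped: int
    slope_name: str = "d_death_rate"
    population_slopes: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "random_effects": {
                "sigma_u2": self.sigma_u2, "sigma_v2": self.sigma_v2,
                "rho": self.rho, "sigma_e2": self.sigma_e2,
            },
            "r2": {"fixed": self.r2_fixed, "total": self.r2_total,
                   "convention": "variance_of_predictions"},
            "state_slopes": self.state_slopes.to_dict(),
            "magnitude_per_1pct": self.magnitude_per_1pct.to_dict(),
            "population_slopes": self.population_slopes,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_dropped": self.n_dropped,
            "extra": self.extra,
        }


def _summarize(model: str, design: Design, res: LMMResult) -> ModelFit:
    beta = res.beta
    slope_fixed = beta.get(design.slope_name, np.nan)
    state_slopes = (res.ranef["slope"] + slope_fixed).rename("total_slope")

    recip = {}
    for name, b in beta.items():
        if name.startswith(("d_", "pc")) and b != 0:
            recip[name] = 1.0 / b
    pop_slopes = {}
    if "log10_pop" in beta.index:
        below = float(beta["log10_pop"])
        above = below + float(beta.get("log10_pop_hinge", 0.0))
        pop_slopes = {"below_knot_per_10fold": below, "above_knot_per_10fold": above}

    return ModelFit(
        model=model,
        coef=beta, se=res.se, pvalues=res.pvalues,
        sigma_u2=res.sigma_u2, sigma_v2=res.sigma_v2, rho=res.rho,
        sigma_e2=res.sigma_e2,
        r2_fixed=res.r2_fixed, r2_total=res.r2_total,
        state_slopes=state_slopes,
        magnitude_per_1pct=pd.Series(recip, name="magnitude_per_1pct"),
        loglik=res.loglik, n_obs=res.n_obs, n_dropped=design.n_dropped,
        slope_name=design.slope_name,
        population_slopes=pop_slopes,
        extra=dict(design.extra, diagonal_fallback=res.diagonal_fallback),
    )


def fit_primary(design: Design, weights: np.ndarray | None = None,
                model_name: str = "primary") -> ModelFit:
    """Fit the multivariable random-slope model on a prepared design."""
    res = fit_lmm(design.y, design.X, design.slope_covariate, design.groups,
                  weights=weights)
    return _summarize(model_name, design, res)


def sensitivity_suite(panel: pd.DataFrame, rate_deltas: pd.DataFrame,
                      pca_variance_fraction: float = 0.9) -> dict[str, ModelFit]:
    """The primary fit plus the three sensitivity analyses.

    1. the model weighted by county population;
    2. the socio-demographic changes replaced by principal components
       retaining ``pca_variance_fraction`` of their variance (the death-rate
       change is kept as-is);
    3. the outcome re-baselined to the 2000 election.
    """
    design = build_design(panel, rate_deltas)
    fits = {"primary": fit_primary(design)}
    fits["weighted"] = fit_primary(design, weights=design.population,
                                   model_name="weighted")
    fits["pca"] = fit_primary(pca_design(design, pca_variance_fraction),
                              model_name="pca")
    design00 = build_design(panel, rate_deltas, outcome="2000_2016")
    fits["baseline2000"] = fit_primary(design00, model_name="baseline2000")
    return fits


def fit_despair_split(panel: pd.DataFrame, rate_deltas_overall: pd.DataFrame,
                      despair_deltas: pd.DataFrame, other_deltas: pd.DataFrame,
                      ) -> ModelFit:
    """Secondary model with despair-rate and other-cause-rate changes."""
    base = build_design(panel, rate_deltas_overall)
    design = despair_split_design(base, despair_deltas, other_deltas)
    return fit_primary(design, model_name="despair_split")
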