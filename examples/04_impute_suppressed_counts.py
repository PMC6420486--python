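"""Bayesian imputation of disclosure-suppressed rare-cause counts.

Counts of 1-9 are withheld by the data provider, leaving interval-censored
cells. A multilevel Poisson model (state and county random intercepts,
period effect, person-years offset) treats each censored count as latent and
draws M completed datasets from the truncated posterior predictive.
Estimates computed per dataset are pooled with Rubin's rules.
"""

import numpy as np

from countyswing import (CensoringRule, GeneratorConfig, ImputationModelSpec,
                         fit_imputation_model, generate_panel, rubin_combine)

data = generate_panel(GeneratorConfig(seed=3, n_states=12, n_counties_total=120))
despair = data.deaths[data.deaths["cause_group"] == "despair"]
print(f"censored cells: {int(despair['suppressed'].sum())} of {len(despair)}")

spec = ImputationModelSpec(chains=4, warmup=600, draws=600, m_datasets=10, seed=7)
imp = fit_imputation_model(despair, CensoringRule(), spec)
print(f"max split-chain R-hat: {imp.diagnostics['max_rhat']:.3f} "
      "(the fit raises instead of returning if this exceeds the threshold)")

# score against the hidden truth the generator kept aside
truth = data.oracle.set_index(["county_id", "period"])["true_count"]
j = imp.summaries.set_index(["county_id", "period"]).join(truth)
mae = np.abs(j["post_mean"] - j["true_count"]).mean()
cover = ((j["true_count"] >= j["q05"]) & (j["true_count"] <= j["q95"])).mean()
print(f"mean absolute error {mae:.2f} vs {np.abs(5 - j['true_count']).mean():.2f} "
      "for a naive midpoint fill of 5")
print(f"90% posterior intervals cover the hidden count in {cover:.1%} of cells")

# Rubin's rules: pool an estimate computed once per completed dataset
means = [d["count"].mean() for d in imp.datasets()]
pooled = rubin_combine(means, [0.01] * imp.m)
print(f"pooled mean cell count {pooled.estimate:.2f} "
      f"(se {pooled.se:.3f}, df {pooled.df:.0f}; the between-imputation term "
      "widens the variance for censored-cell uncertainty)")
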