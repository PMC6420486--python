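"""Generate a synthetic county panel and look at its structure.

The generator emulates ~3,100 US counties nested in 50 states: right-skewed
populations, six urban-rural classes, covariates at 2000 and 2015, vote
shares for three elections, and death tables with a censored rare-cause
stream. Truth needed only for validation (state effects, suppressed counts)
is kept out of the public tables.
"""

import numpy as np

from countyswing import GeneratorConfig, generate_panel

data = generate_panel(GeneratorConfig(seed=1))
panel, deaths = data.panel, data.deaths

print(f"counties: {len(panel)}, states: {panel['state_id'].nunique()}")
q = np.percentile(panel["population"], [5, 50, 95]).astype(int)
print(f"population 5/50/95th percentile: {q[0]:,} / {q[1]:,} / {q[2]:,}")
print("urban-rural class counts (1=large central metro ... 6=noncore):")
print(panel["urban_rural"].value_counts().sort_index().to_string())

despair = deaths[deaths["cause_group"] == "despair"]
print(f"\nrare-cause cells suppressed: {despair['suppressed'].mean():.1%} "
      f"(true values of censored cells live in a separate oracle table, "
      f"n={len(data.oracle)})")
# Small counties produce small counts, so suppression concentrates there;
# the oracle table lets tests score the imputation against hidden truth.
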