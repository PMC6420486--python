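"""The multivariable random-slope model and the swing-state counterfactual.

Net Republican gain is regressed on 2000->2015 covariate changes, a rural
indicator, and a piecewise log10(population) term, with a state random
intercept and a state random slope on the death-rate change (bivariate
normal). Each state's total slope, inverted, says how many deaths per
100,000 correspond to one point of net gain; multiplied by a victory margin
it gives the death-rate reduction associated with erasing that margin.
"""

from countyswing import (GeneratorConfig, age_adjust, generate_panel,
                         rate_deltas, required_reduction, sensitivity_suite,
                         state_slope)
from countyswing.standards import us2000_standard_million

data = generate_panel(GeneratorConfig(seed=1))
std = us2000_standard_million()
allcause = data.deaths[data.deaths["cause_group"] == "all_cause"]
fits = sensitivity_suite(data.panel, rate_deltas(age_adjust(allcause, std)))

primary = fits["primary"]
print("death-rate change per 1 point of net gain (reciprocal slope):")
for name, fit in fits.items():
    print(f"  {name:13s} {1 / fit.coef[fit.slope_name]:6.0f} per 100,000")
print(f"\nrandom effects: state-intercept var {primary.sigma_u2:.1f}, "
      f"state-slope var {primary.sigma_v2:.2e}, correlation {primary.rho:.2f}")
print(f"R^2 fixed effects only {primary.r2_fixed:.2f}; "
      f"fixed + random {primary.r2_total:.2f}")

# counterfactual for the state with the smallest positive reciprocal slope
some_state = primary.state_slopes.idxmax()
slope = state_slope(primary, some_state)
cf = required_reduction(slope, victory_margin=0.5, state_id=some_state)
print(f"\nstate {some_state}: {slope:.0f}/100,000 per 1% gain; a 0.5-point "
      f"margin corresponds to a {cf.required_reduction_rounded}/100,000 "
      "death-rate reduction (association-based, not causal)")

# the published swing-state arithmetic, from printed slopes and margins
for st, sl, mg in (("Michigan", 80, 0.22), ("Pennsylvania", 61, 0.72),
                   ("Wisconsin", 88, 0.76)):
    cf = required_reduction(sl, mg, state_id=st)
    print(f"  {st:13s} margin {mg:.2f} x {sl}/100k -> "
          f"{cf.required_reduction_rounded}/100,000")
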