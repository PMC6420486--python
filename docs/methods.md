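# Methods

This note documents the statistical machinery in `countyswing`: the models,
their assumptions, the defaults and why, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer would want
written down.

## Outcome and design

The outcome is the net Republican percentage gain
`g = (R16 − R08) + (D08 − D16)` in percentage points, a *signed* sum: no
positive-part truncation is applied, because observed county swings include
negative values and truncation would make those impossible. Exact ties in a
party's share count as "no gain" for that party; a county tied in both
parties falls into the both-decline class with a logged warning.

Covariates enter as 2015 − 2000 differences in natural units (years,
percentage points, thousands of dollars, deaths per 100,000). Population
enters as log10 with a hinge basis `{log10(pop), max(0, log10(pop) −
log10(50,000))}`; the hinge parameterization guarantees continuity at the
knot by construction, and the below-knot slope is the first coefficient
while the above-knot slope is the sum of both. The rural indicator
binarizes the six ordered urban–rural classes as 5–6 (micropolitan +
noncore) = rural; the cut is configurable since definitions vary. Counties
missing any covariate are dropped (complete-case) with the exclusion count
logged.

## The mixed model

The multivariable model has a state random intercept and a state random
slope on the death-rate change, jointly bivariate normal with free
correlation, plus homoskedastic county noise. It is fit by **maximum
likelihood** (not REML) so that the variance-explained decomposition and
nested-model comparisons are coherent; with ~3,000 counties the REML/ML
difference in the fixed effects is negligible.

Implementation: the four variance parameters (log σ_u, log σ_v, atanh ρ,
log σ_e) are optimized by L-BFGS-B on the profiled likelihood — for any
candidate the GLS β is closed-form, so the search space stays
four-dimensional. The random-slope covariate is standardized internally for
conditioning and the components are rescaled on exit. Two starting points
guard against local optima; a fitted |ρ| ≳ 1 triggers an automatic refit
with diagonal covariance and a prominent warning. Observation weights (the
population-weighted sensitivity fit) enter as residual precision weights
σ²/w_i, normalized to mean 1; with equal weights the computation is
bit-identical to the unweighted fit. statsmodels MixedLM cannot carry such
weights, which is why the fitter is in-house; the unweighted fit is
cross-checked against MixedLM in the test suite.

Two R² conventions exist for mixed models (variance-of-predictions vs
squared correlation); the package reports the **variance-of-predictions**
convention and names it in its output: R²_fixed = var(Xβ̂)/var(y), R²_total
adds the BLUP random-effect predictions. For weighted fits both variances
are computed in the weighted metric, which keeps the decomposition
internally consistent.

The reciprocal presentation ("magnitude of covariate change per 1 point of
net gain" = 1/coefficient) is computed alongside the raw coefficients and
verified programmatically to satisfy `magnitude × coefficient = 1`.

Sensitivity analyses: (1) weights = county population; (2) the eight
socio-demographic changes standardized and replaced by principal
components retaining a configurable variance fraction (default 0.9; at 1.0
the rotation spans the same column space and the fit is identical); (3) the
outcome re-baselined to the 2000 election. A secondary variant splits the
death-rate change into the rare-cause ("despair") stream and all other
causes; it runs once per imputed dataset and pools by Rubin's rules, with
the random slope carried by the dominant other-cause change.

## Clustered comparisons

Group-mean comparisons use a linear model with a state random intercept.
Because this model has a single variance ratio λ = τ²/σ², the REML
criterion is profiled exactly (closed-form block inverses,
one-dimensional bounded optimization including the λ = 0 boundary); at the
boundary the fit collapses to ordinary least squares with the usual n − p
denominator, so the group test reduces to the classical pooled two-sample
test — a limit the test suite checks to 1e-6. P-values use the large-sample
normal reference; with thousands of counties the t/normal distinction is
immaterial and is documented rather than corrected. No multiple-testing
adjustment is applied across the table of comparisons, mirroring common
practice for descriptive tables; this is a deliberate non-goal.

The two-election question ("did the gap widen?") is a 3-level model —
value ~ group × election with county-within-state nested random intercepts —
fit with statsmodels MixedLM (variance components for counties); the
interaction contrast is the change in the gap.

## Censored-count imputation

Disclosure rules suppress counts of 1–9 (zero counts are published: a zero
reveals no individual). A suppressed cell is therefore interval-censored on
[1, 9]. The model is the minimal multilevel structure consistent with the
censoring: Poisson counts with a person-years offset, a period effect, and
nested normal random intercepts (state, county), with weakly informative
normal priors on the fixed effects and half-normal(1) priors on the
random-effect scales. The rare-cause stream is modelled at the
county × period aggregate level (a single all-ages stratum with
person-years = population): age-specific cells of a rare cause would be
almost universally suppressed, and the aggregate level is what the
downstream rate contrast needs. The "age-adjusted" rate of this stream is
its crude rate; the all-cause stream keeps its 11 age strata.

Sampling is a Metropolis-within-Gibbs scheme vectorized across chains:

* censored counts are latent and resampled each sweep from the truncated
  Poisson (inverse-cdf over the 9 support points), so the M completed
  datasets are integer draws from the truncated posterior predictive —
  count-consistent for direct standardization downstream;
* county and state intercept blocks use **Gamma independence proposals**:
  the Poisson conditional for exp(effect) is exactly Gamma, so the proposal
  matches the likelihood and the acceptance ratio reduces to the normal
  prior (a +0.5 shape offset keeps the proposal proper at zero counts);
* the random-effect scales are drawn from their exact univariate
  conditionals on a fixed log-scale grid (inverse-cdf, no random-walk lag);
* translation moves along likelihood-invariant ridges (intercept vs effect
  blocks) and non-centered block-rescaling moves (scale proposed with
  standardized effects held fixed) keep the hierarchy mixing — the latter
  is the move that crosses the classic funnel geometry.

Defaults: 4 chains × 1,000 post-warmup draws after 1,000 warmup sweeps
(proposal scales adapt during warmup only), M = 10 completed datasets taken
at evenly spaced positions across the pooled draws. Convergence is
monitored by split-chain R-hat (arviz) on the fixed effects, both log
scales and the mean county effect; exceeding the threshold (default 1.05)
raises an error carrying the diagnostics instead of returning silently bad
imputations. On study-scale panels (~3,000 censored cells) a run takes
tens of seconds and R-hat typically sits at 1.01–1.04.

Rubin's rules pool estimates computed once per completed dataset: combined
estimate = mean, total variance = mean within-variance + (1 + 1/M) × between
variance, with the classical small-sample degrees of freedom (infinite when
the estimates agree exactly). The combiner is checked against an
independently coded version to 1e-12.

## Counterfactual

A state's total death-rate slope (fixed coefficient + BLUP random slope) is
inverted to deaths per 100,000 per point of net gain and multiplied by the
state's victory margin in points. Reported values are rounded half-up to
integers per 100,000 (full precision is kept internally). A non-positive or
near-zero total slope is refused — the reciprocal is unstable and the
counterfactual direction undefined. All outputs carry the label
"association-based, not causal".

## Synthetic generator

The generator's defaults encode the study conditions: 3,112 counties in 50
states (counties per state from log-normal weights, so state sizes are
skewed), county populations log10-normal(4.35, 0.65) with a floor of 300,
urban–rural classes cut at 10k/50k/250k/1M/4M, covariate levels and
2000→2015 changes drawn to match the published county distributions, and
generating coefficients equal to the reciprocals of the published
"magnitude per 1% gain" values (death-rate slope 1/131 per 100,000). State
effects are bivariate normal with intercept SD 7.87 (variance ≈ 62), slope
SD 0.004 and correlation 0.49; the slope SD is chosen so the per-state
reciprocal slopes span the published 61–131 family (the printed slope
"variance of 0.70" is dimensionally inconsistent with the per-100,000 scale
those reciprocals imply, so the reciprocals were taken as authoritative).
Residual SD 6 and an intercept of 35.6 center the county net gain near the
observed median of 15 points.

All-cause deaths are Poisson draws around a US-like age-rate schedule
scaled to each county's latent target rate (baseline ~N(920, 145), change
~N(−74, 127) per 100,000); the *realized* standardized-rate change (counts,
not the latent target) drives the vote outcome, so refitting from the
emitted tables recovers the generating coefficients without
errors-in-variables attenuation. The rare-cause stream has baseline rate
~N(22, 12) and trend ~N(20, 15) per 100,000, weakly coupled (0.06) to the
county's all-cause change so rare-cause increases concentrate where overall
declines are slow; counts of 1–9 are flagged suppressed, their true values
written to a separate oracle table that never enters the public output.
Vote shares decompose the generated swing into a Republican rise and a
Democratic fall (the Democratic share absorbs ~65%, third-party growth the
rest) under feasibility bounds that preserve the net-gain identity exactly;
counties with no feasible split (a handful per run at most) are clipped and
logged. Vote counts are shares × turnout (42% of population ± jitter),
rounded.

What the generator does **not** emulate: spatial adjacency and geographic
realism, correlated covariate changes beyond their link through the
outcome, turnout dynamics, third-party candidate behavior beyond a residual
share, and overdispersion beyond Poisson in death counts. Passing
recovery/calibration tests therefore demonstrates correctness of the
estimators under the generating assumptions, not robustness to real-data
features outside them.

## Problem sizes in the test and acceptance suites

Unit tests run on 120-county/12-state and 600-county/30-state panels.
Recovery checks run 20 replicates at full study scale (3,112 counties / 50
states); imputation calibration pools 20 seeded small-panel runs
(4 × 600 + 600 sweeps each); the clustered-test size check uses 600–800
null replicates of 40 states × 5 counties. These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping the whole suite
at a few minutes.

## Known limitations

* The imputation model conditions on no covariates beyond period and the
  nested intercepts; real suppression patterns may correlate with omitted
  county characteristics.
* BLUP-based per-state slopes shrink toward the fixed slope; counterfactual
  reductions for small states inherit that shrinkage.
* The ecological design carries no individual-level interpretation, and the
  counterfactuals are associations, not causal estimates — the code labels
  them as such.
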