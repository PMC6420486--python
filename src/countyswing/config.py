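"""Configuration dataclasses for the generator, censoring and imputation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default per-covariate (level_2000_mean, level_2000_sd, change_mean, change_sd)
#: in natural units: years, percentage points, $1000s; chosen to match the
#: county-level distributions the comparison tables describe.
DEFAULT_COVARIATE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "age": (37.4, 3.7, 3.9, 2.5),
    "black": (9.0, 14.0, 0.6, 1.8),
    "hispanic": (5.3, 10.6, 2.7, 2.7),
    "asian": (0.9, 2.8, 0.6, 0.8),
    "income": (36.5, 8.0, 10.5, 5.1),
    "unemployment": (4.4, 1.7, 1.2, 1.2),
    "bachelor": (15.0, 5.9, 4.2, 2.7),
    "insured": (85.4, 4.9, 5.5, 3.5),
}

#: default generating coefficients, percentage points of net gain per unit
#: change; signs follow the fitted direction of each covariate (negative for
#: diversity, income, unemployment, education and insurance increases;
#: positive for a slower death-rate decline).
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "age": 1 / 44.51,
    "black": -1 / 3.86,
    "hispanic": -1 / 2.35,
    "asian": -1 / 0.72,
    "income": -1 / 7.504,
    "unemployment": -1 / 3.49,
    "bachelor": -1 / 1.99,
    "insured": -1 / 2.56,
    "death_rate": 1 / 131.0,
    "rural": 3.53,
    "log10_pop": -2.97,        # below-knot slope per 10-fold population
    "log10_pop_above": -7.21,  # above-knot slope per 10-fold population
    "intercept": 35.6,         # centers the net gain near the observed median ~15
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic county-panel generator.

    Defaults emulate the study conditions: ~3,112 counties in 50 states,
    heavy-right-skewed populations (log10 pop ~ N(4.35, 0.65)), state-level
    clustering of the vote swing with a correlated random intercept/slope
    pair, all-cause death rates near 920 per 100,000 in 2000 declining ~74
    on average by 2015, and a rare "deaths of despair" stream whose small
    counts are suppressed below the disclosure threshold.
    """

    n_states: int = 50
    n_counties_total: int = 3112
    seed: int = 0

    population_log10_mean: float = 4.35
    population_log10_sd: float = 0.65
    population_min: int = 300
    #: ascending cutoffs mapping population to the 6 urban-rural classes
    #: (class 6 = smallest noncore to class 1 = large central metro)
    urban_thresholds: tuple = (10_000, 50_000, 250_000, 1_000_000, 4_000_000)

    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    true_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS))

    sigma_state_intercept: float = 7.87
    sigma_state_slope: float = 0.004
    rho_intercept_slope: float = 0.49
    sigma_residual: float = 6.0

    baseline_death_rate_mean: float = 920.0
    baseline_death_rate_sd: float = 145.0
    death_rate_change_mean: float = -74.0
    death_rate_change_sd: float = 127.0

    #: rare-cause stream: baseline rate (per 100,000) mean/sd and 2000->2015
    #: trend mean/sd
    despair_rate_params: tuple = (22.0, 12.0, 20.0, 15.0)
    #: coupling of the rare-cause trend to the county's all-cause rate change
    #: (per 100,000 of despair trend per 100,000 of all-cause change), so
    #: counties with slower overall declines also see larger despair increases
    despair_link: float = 0.06

    suppression_threshold: int = 10
    turnout_fraction: float = 0.42

    def validate(self) -> None:
        if self.n_states < 2 or self.n_counties_total < self.n_states:
            raise ValueError("need >= 2 states and at least one county per state")
        if self.population_log10_mean <= 0 or self.population_log10_sd <= 0:
            raise ValueError("population scale parameters must be positive")
        for nm in ("sigma_state_intercept", "sigma_state_slope", "sigma_residual"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if self.sigma_residual == 0 and (self.sigma_state_intercept or self.sigma_state_slope):
            pass  # noise-free fixed part with random effects is allowed
        if abs(self.rho_intercept_slope) > 1:
            raise ValueError("|rho_intercept_slope| must be <= 1")
        th = np.asarray(self.urban_thresholds)
        if len(th) != 5 or np.any(np.diff(th) <= 0):
            raise ValueError("urban_thresholds must be 5 strictly increasing cutoffs")
        if self.suppression_threshold < 1:
            raise ValueError("suppression_threshold must be >= 1")


@dataclass(frozen=True)
class CensoringRule:
    """Disclosure suppression: counts inside [lower, threshold - 1] are withheld."""

    threshold: int = 10
    lower: int = 1

    def __post_init__(self):
        if self.lower not in (0, 1):
            raise ValueError("censoring interval lower bound must be 0 or 1")
        if self.threshold <= self.lower:
            raise ValueError("threshold must exceed the interval lower bound")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.lower, self.threshold - 1)


@dataclass
class ImputationModelSpec:
    """Interval-censored Poisson imputation model and its MCMC settings.

    Likelihood: count ~ Poisson(exp(eta) * person_years) with
    eta = intercept + period_effect * 1[period = later] + state intercept +
    county intercept; normal random effects with half-normal scale priors;
    censored cells contribute the Poisson mass over the censoring interval.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    m_datasets: int = 10
    seed: int = 0
    prior_intercept: tuple = (-8.0, 3.0)     # normal(mean, sd) on log rate
    prior_period: tuple = (0.0, 2.0)
    prior_scale_sd: float = 1.0              # half-normal sd for RE scales
    rhat_threshold: float = 1.05

    def validate(self) -> None:
        if self.m_datasets < 2:
            raise ValueError("at least 2 imputed datasets are required")
        if self.chains * self.draws < self.m_datasets:
            raise ValueError("chains * draws must be >= m_datasets")
        if self.warmup < 0 or self.draws < 1 or self.chains < 1:
            raise ValueError("invalid MCMC settings")
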