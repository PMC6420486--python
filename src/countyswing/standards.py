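"""Standard populations for direct age standardization.

The default is the US 2000 standard million in the 11 age groups used by
CDC WONDER for age-adjusted county death rates: weights are proportions of
a reference population, and a directly standardized rate is the
weight-averaged stratum rate expressed per 100,000.
"""

from __future__ import annotations

import pandas as pd

#: Ordered 11-group age partition (CDC WONDER convention).
AGE_GROUPS = (
    "<1", "1-4", "5-14", "15-24", "25-34", "35-44",
    "45-54", "55-64", "65-74", "75-84", "85+",
)

# US 2000 standard million (Census 2000 projected population, per million).
_STANDARD_MILLION = (
    13818, 55317, 145565, 138646, 135573, 162613,
    134834, 87247, 66037, 44842, 15508,
)


def us2000_standard_million() -> pd.DataFrame:
    """Return the US 2000 standard population as (age_group, weight) rows.

    Weights sum to 1 exactly (the standard million sums to 1,000,000).
    """
    return pd.DataFrame(
        {"age_group": AGE_GROUPS, "weight": [w / 1_000_000 for w in _STANDARD_MILLION]}
    )


def load_standard(path) -> pd.DataFrame:
    """Load a standard population CSV with columns age_group, weight."""
    std = pd.read_csv(path)
    missing = {"age_group", "weight"} - set(std.columns)
    if missing:
        raise ValueError(f"standard population file lacks columns: {sorted(missing)}")
    total = std["weight"].sum()
    if abs(total - 1.0) > 1e-6:
        std = std.assign(weight=std["weight"] / total)
    return std[["age_group", "weight"]]
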