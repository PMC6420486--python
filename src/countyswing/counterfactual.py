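"""Swing-state counterfactual: death-rate reduction that would offset a margin.

The multivariable model yields, per state, a slope linking death-rate change
to net Republican gain. Inverted, that slope says how many deaths per 100,000
correspond to one percentage point of net gain. Multiplying by a state's
victory margin gives the hypothetical death-rate reduction associated with
erasing that margin. These are association-based quantities, not causal
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_up


@dataclass(frozen=True)
class CounterfactualResult:
    """Per-state counterfactual: association-based, not causal."""

    state_id: str
    #: deaths per 100,000 associated with 1 point of net Republican gain
    slope_per_1pct: float
    #: winning margin in percentage points
    victory_margin: float
    #: death-rate reduction (per 100,000) that would offset the margin, full precision
    required_reduction: float
    #: reduction rounded to the nearest integer per 100,000 (half-up), for reporting
    required_reduction_rounded: int


def required_reduction(slope_per_1pct: float, victory_margin: float,
                       state_id: str = "") -> CounterfactualResult:
    """Death-rate reduction per 100,000 associated with erasing a victory margin.

    ``slope_per_1pct`` is in death-rate units (per 100,000) per point of net
    gain; ``victory_margin`` in points. Both must be non-negative, and the
    slope strictly positive: a negative slope would make the counterfactual
    direction undefined.
    """
    if slope_per_1pct <= 0:
        raise ValueError(
            f"slope_per_1pct must be > 0 (got {slope_per_1pct}); a non-positive slope "
            "leaves the counterfactual direction undefined"
        )
    if victory_margin < 0:
        raise ValueError("victory_margin must be >= 0")
    red = slope_per_1pct * victory_margin
    return CounterfactualResult(
        state_id=state_id,
        slope_per_1pct=float(slope_per_1pct),
        victory_margin=float(victory_margin),
        required_reduction=float(red),
        required_reduction_rounded=int(round_half_up(red, 0)),
    )


def state_slope(fit, state_id: str, min_slope: float = 1e-4) -> float:
    """Deaths per 100,000 per 1 point of net gain for one state.

    ``fit`` is a :class:`~countyswing.model.ModelFit`; the state's total
    death-rate slope is the fixed coefficient plus the state's predicted
    random slope (points of gain per unit death-rate change), and the
    returned value is its reciprocal. A total slope below ``min_slope``
    (points per unit per 100,000) is refused: the reciprocal is unstable.
    """
    if state_id not in fit.state_slopes.index:
        raise KeyError(f"state {state_id!r} not present in fit")
    total = float(fit.state_slopes.loc[state_id])
    if total <= min_slope:
        raise ValueError(
            f"state {state_id!r} total death-rate slope {total:.3g} is non-positive or "
            "too close to zero for a stable reciprocal"
        )
    return 1.0 / total
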