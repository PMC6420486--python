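"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x, decimals: int = 0):
    """Round with ties going away from zero on the positive side (half-up).

    Published tables use conventional half-up rounding (15.46 -> 15, 83.75 -> 83.8),
    not banker's rounding, so ``np.round`` is not a drop-in.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.floor(x * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def spawn_seed(seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from a global seed and a stage name.

    Stages of the pipeline draw from independent streams so any single stage
    can be re-run in isolation and reproduce the full-run result.
    """
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "little") % (2**63)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
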