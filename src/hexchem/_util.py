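"""Small numeric helpers shared across the engine."""

from __future__ import annotations

import numpy as np

#: Guard against float products like ``b * r`` landing one ulp below an
#: integer value.  Residual rates and reaction probabilities have at most a
#: few decimal places, so any true fractional part is far larger than this.
FLOOR_EPS = 1e-9


def floor_int(x: np.ndarray | float) -> np.ndarray:
    """Round-down to int64 with the one-ulp guard."""
    return np.floor(np.asarray(x, dtype=np.float64) + FLOOR_EPS).astype(np.int64)


def stochastic_round(x, rng: np.random.Generator) -> np.ndarray:
    """Integer draw with mean ``x``: ``floor(x)`` plus one more with
    probability ``frac(x)``.  Vectorised; returns int64 of ``x``'s shape."""
    x = np.asarray(x, dtype=np.float64)
    base = floor_int(x)
    frac = x - base
    extra = rng.random(x.shape) < frac
    return base + extra
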