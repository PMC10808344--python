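"""Energy metabolism: resource supply, catalysed production, consumption,
waste removal.

Energy flows through three species: resource molecule 20 is re-supplied in
quanta of ``E`` to any cell whose stock has hit zero; informant polymers
whose sequences carry the five-consecutive molecule-6 motif catalyse the
conversion 20 -> 25 (the usable energy carrier); every energy-costing
network reaction converts 25 -> 19; and waste molecule 19 is removed from
the lattice at the end of every step, closing the flow.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, MutableMapping, Sequence

import numpy as np

from ._util import stochastic_round
from .state import LatticeState
from .species import ENERGY, RESOURCE, WASTE

RATE_SLOPE = 4.0       #: slope of the linear catalytic-rate map
RATE_INTERCEPT = -0.6  #: intercept; the map is clamped to [0, 1]


@dataclass(frozen=True)
class EnergyParams:
    """Energy-metabolism constants.  ``E`` is the resource quantum supplied
    to exhausted cells (the sweep variable, 200-800 in the standard
    experiments); one molecule 25 is consumed per converted molecule."""

    E: int = 800
    rate_slope: float = RATE_SLOPE
    rate_intercept: float = RATE_INTERCEPT
    consumption_per_event: int = 1

    def __post_init__(self):
        if self.E < 0:
            raise ValueError(f"E={self.E} must be >= 0")


@dataclass(frozen=True)
class EnergySchedule:
    """Piecewise-constant resource quantum over time.

    ``entries`` is an ordered list of ``(from_step, E)`` pairs, the first at
    step 0 and steps strictly increasing.  A new value applies from
    ``from_step + 1`` onward — "reduced after step 4000" means step 4000
    still gets the old quantum.
    """

    entries: tuple[tuple[int, int], ...] = ((0, 800),)

    def __post_init__(self):
        if not self.entries or self.entries[0][0] != 0:
            raise ValueError("schedule must start with an entry at step 0")
        steps = [s for s, _ in self.entries]
        if steps != sorted(set(steps)):
            raise ValueError("schedule steps must be strictly increasing")
        if any(e < 0 for _, e in self.entries):
            raise ValueError("negative E in schedule")

    @classmethod
    def constant(cls, E: int) -> "EnergySchedule":
        return cls(((0, int(E)),))


def scheduled_E(schedule: EnergySchedule, step: int) -> int:
    """Resource quantum in force at ``step`` (new entries take effect the
    step after their ``from_step``)."""
    if step < 0:
        raise ValueError(f"negative step {step}")
    steps = [s for s, _ in schedule.entries]
    i = bisect_left(steps, step)  # first entry with from_step >= step
    return schedule.entries[max(i - 1, 0)][1]


def energy_production_rate(c, slope: float = RATE_SLOPE, intercept: float = RATE_INTERCEPT):
    """Per-step probability that a resource molecule converts to an energy
    molecule, given catalytic ratio ``c``: ``clamp(4.0*c - 0.6, 0, 1)``.

    Zero at and below c = 0.15, 0.60 at c = 0.30, saturating at c = 0.40.
    Accepts scalars or arrays; rejects c outside [0, 1].
    """
    arr = np.asarray(c, dtype=np.float64)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError(f"catalytic ratio outside [0, 1]: {c!r}")
    rate = np.clip(slope * arr + intercept, 0.0, 1.0)
    return float(rate) if np.isscalar(c) or arr.ndim == 0 else rate


def produce_energy(
    state: LatticeState,
    rng: np.random.Generator,
    params: EnergyParams = EnergyParams(),
) -> int:
    """Catalysed 20 -> 25 conversion.

    Fires only in cells hosting at least one informant polymer; the cell's
    rate is the linear map applied to the arithmetic mean of its residents'
    catalytic ratios, and the number of converted molecules is the
    stochastic rounding of ``count20 * rate``.  Returns total production.
    """
    counts = state.counts_view()
    c20 = counts[RESOURCE]
    if len(state.polymers) == 0:
        return 0
    n = state.grid.n_cells
    pcount = state.polymers.counts_per_cell(n).reshape(c20.shape)
    mean_c = state.polymers.mean_ratio_per_cell(n).reshape(c20.shape)
    rate = np.clip(params.rate_slope * mean_c + params.rate_intercept, 0.0, 1.0)
    rate[pcount == 0] = 0.0
    conv = np.minimum(stochastic_round(c20 * rate, rng), c20)
    c20 -= conv
    counts[ENERGY] += conv
    return int(conv.sum())


def consume_energy(counts: MutableMapping[int, np.ndarray], events, cost: int = 1):
    """Grant an event budget against the molecule-25 stock.

    ``min(events, count25 // cost)`` events are granted; the corresponding
    molecules 25 become molecule 19.  Returns the granted budget (same shape
    as ``events``), which callers use to truncate reaction applications.
    """
    events = np.asarray(events, dtype=np.int64)
    if (events < 0).any():
        raise ValueError("negative event request")
    if cost <= 0:
        return events
    granted = np.minimum(events, counts[ENERGY] // cost)
    spent = granted * cost
    counts[ENERGY] -= spent
    counts[WASTE] += spent
    return granted


def supply_resource(state: LatticeState, E: int) -> int:
    """Deposit ``E`` resource molecules into every cell whose molecule-20
    count is exactly zero.  Returns the total influx (E x number of
    exhausted cells, the ledger quantity)."""
    if E < 0:
        raise ValueError(f"E={E} must be >= 0")
    c20 = state.counts_view()[RESOURCE]
    mask = c20 == 0
    c20[mask] += E
    return int(E * mask.sum())


def remove_waste(state: LatticeState) -> int:
    """Clear molecule 19 from every cell; returns the removed total."""
    c19 = state.counts_view()[WASTE]
    removed = int(c19.sum())
    c19[...] = 0
    return removed
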