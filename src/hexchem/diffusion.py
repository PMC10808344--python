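"""Diffusion operators on the hexagonal lattice.

A species with residual rate ``r`` keeps ``floor(b*r)`` molecules in each
cell, sends ``floor(b*(1-r)/6)`` to each of the six neighbours, and scatters
the integer remainder one molecule at a time to uniformly random neighbours.
Totals are conserved exactly (pure integer bookkeeping).  Polymers diffuse as
whole boxes: each instance stays with probability ``r`` or moves intact to a
uniformly random neighbour.
"""

from __future__ import annotations

import numpy as np

from ._util import FLOOR_EPS
from .grid import N_DIRECTIONS
from .state import LatticeState

_PVALS = np.full(N_DIRECTIONS, 1.0 / N_DIRECTIONS)


def _check_r(r: float) -> float:
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"residual rate {r} outside [0, 1]")
    return float(r)


def diffuse(state: LatticeState, species_id: int, r: float, rng: np.random.Generator) -> LatticeState:
    """One diffusion step for one species, in place.  Draw order: a single
    multinomial scatter of each cell's remainder over the six directions."""
    _check_r(r)
    b = state.counts[state.species_index(species_id)]
    if (b < 0).any():
        raise ValueError("negative count before diffusion")
    if r == 1.0 or not b.any():
        return state

    stay = np.floor(b * r + FLOOR_EPS).astype(np.int64)
    share = np.floor(b * (1.0 - r) / N_DIRECTIONS + FLOOR_EPS).astype(np.int64)
    rem = b - stay - N_DIRECTIONS * share  # 0..6 per cell

    perms = state.grid.neighbor_perms()
    new = stay
    flat_share = share.ravel()
    if share.any():
        inflow = np.zeros(b.size, dtype=np.int64)
        for d in range(N_DIRECTIONS):
            inflow[perms[d]] += flat_share
        new = new + inflow.reshape(b.shape)
    if rem.any():
        scatter = rng.multinomial(rem.ravel(), _PVALS)  # (n_cells, 6)
        inflow = np.zeros(b.size, dtype=np.int64)
        for d in range(N_DIRECTIONS):
            inflow[perms[d]] += scatter[:, d]
        new = new + inflow.reshape(b.shape)
    b[...] = new
    return state


def diffuse_all_species(state: LatticeState, residual_rates: dict[int, float], rng: np.random.Generator) -> None:
    """Diffuse every species in ascending-id order (the documented draw
    order for reproducibility)."""
    for sid in state.species_ids:
        diffuse(state, sid, residual_rates[sid], rng)


def diffuse_polymers(state: LatticeState, r: float, rng: np.random.Generator) -> LatticeState:
    """Move informant-polymer boxes: each instance independently stays with
    probability ``r`` or relocates, sequence untouched, to a uniformly random
    neighbour.  Instance count is conserved."""
    _check_r(r)
    pop = state.polymers
    n = len(pop)
    if n == 0 or r == 1.0:
        return state
    moves = rng.random(n) < (1.0 - r)
    dirs = rng.integers(0, N_DIRECTIONS, size=int(moves.sum()))
    perms = state.grid.neighbor_perms()
    cells = pop.cells
    cells[moves] = perms[dirs, cells[moves]]
    return state


def diffuse_boxes2(state: LatticeState, r: float, rng: np.random.Generator) -> LatticeState:
    """Move boundary boxes (count representation): binomial split of movers,
    multinomial scatter over the six directions."""
    _check_r(r)
    b = state.boxes2
    if r == 1.0 or not b.any():
        return state
    movers = rng.binomial(b, 1.0 - r)
    if movers.any():
        scatter = rng.multinomial(movers.ravel(), _PVALS)
        perms = state.grid.neighbor_perms()
        inflow = np.zeros(b.size, dtype=np.int64)
        for d in range(N_DIRECTIONS):
            inflow[perms[d]] += scatter[:, d]
        b -= movers
        b += inflow.reshape(b.shape)
    return state
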