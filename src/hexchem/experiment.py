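"""Trial driver: full per-step update loop, observers, survival detection
and replicate sweeps over energy supply and mutation rate.

One synchronous step applies, in order: (1) diffusion of every species and
both polymer types; (2) the reaction network with energy truncation;
(3) boundary-box formation/decomposition and informant decay; (4) informant
replication with mutation; (5) catalysed energy production; (6) waste
removal; (7) resource supply to exhausted cells.  A single seeded random
stream drives the whole trial with a fixed draw order, so a (config, seed)
pair reproduces bit-identical results across process restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffusion import diffuse_all_species, diffuse_boxes2, diffuse_polymers
from .energy import (
    EnergySchedule,
    produce_energy,
    remove_waste,
    scheduled_E,
    supply_resource,
)
from .grid import HexGrid
from .polymers import (
    PolymerParams,
    PolymerTriggers,
    decay_polymers1,
    decompose_boxes,
    form_boxes,
    mutate_residents,
    random_polymer1,
    replicate_polymers1,
)
from .reactions import ReactionNetwork, apply_network, default_network
from .species import MOLECULE_IDS
from .state import LatticeState
from .species import SpeciesTable, standard_species_table

SURVIVED = "survived"
EXTINCT = "extinct"


@dataclass(frozen=True)
class TrialConfig:
    """Everything one trial needs.  Defaults are the standard case: 100x100
    grid, E = 800, mutation rate 0.1, 8000 steps."""

    width: int = 100
    height: int = 100
    species: SpeciesTable = field(default_factory=standard_species_table)
    network: ReactionNetwork | None = None  # None -> bundled default
    triggers: PolymerTriggers | None = None
    params: PolymerParams = field(default_factory=PolymerParams)
    energy: EnergySchedule = field(default_factory=lambda: EnergySchedule.constant(800))
    max_steps: int = 8000
    seed: int = 0
    central_radius: int = 3

    def resolved(self) -> "TrialConfig":
        if self.network is not None and self.triggers is not None:
            return self
        net, trig = default_network()
        return replace(
            self,
            network=self.network if self.network is not None else net,
            triggers=self.triggers if self.triggers is not None else trig,
        )


@dataclass
class StepLedger:
    """Per-step mass-flow audit: every route by which a species total can
    change.  Diffusion appears nowhere because it conserves exactly."""

    reaction_events: int = 0
    energy_produced: int = 0
    waste_removed: int = 0
    resource_supplied: int = 0
    boxes_formed: int = 0
    boxes_decomposed: int = 0
    polymers_created: int = 0
    polymers_decayed: int = 0


@dataclass
class TrialResult:
    """Per-step time series plus the survival outcome."""

    series: pd.DataFrame
    outcome: str
    extinction_step: int | None
    seed: int
    final_mean_ratio: float  # population mean catalytic ratio at the last step
    final_state: LatticeState | None = None

    @property
    def survived(self) -> bool:
        return self.outcome == SURVIVED


def initialize(config: TrialConfig, rng: np.random.Generator) -> LatticeState:
    """Standard initial condition: the species table's global counts in
    every cell, central-area overrides in a hex disk around the lattice
    centre, and the seeded informant polymers distributed round-robin over
    the innermost central cells."""
    grid = HexGrid(config.width, config.height)
    state = LatticeState(grid)
    for s in config.species.rows:
        state.counts[state.species_index(s.species_id)][...] = s.initial_global
    center = grid.flat(grid.height // 2, grid.width // 2)
    central = grid.disk(center, config.central_radius)
    flat_idx = np.array(central, dtype=np.int64)
    for s in config.species.rows:
        if s.initial_central is not None:
            view = state.counts[state.species_index(s.species_id)].ravel()
            view[flat_idx] = s.initial_central
    n_poly = config.species.polymer1_initial_central
    if n_poly > 0:
        cells = [central[i % len(central)] for i in range(n_poly)]
        seqs = np.stack([random_polymer1(config.params.w, rng) for _ in range(n_poly)])
        state.polymers.add(np.array(cells, dtype=np.int64), seqs)
    state.validate()
    return state


def step(state: LatticeState, config: TrialConfig, rng: np.random.Generator) -> StepLedger:
    """Advance the state by one synchronous update (in place)."""
    config = config.resolved()
    ledger = StepLedger()
    rates = {s.species_id: s.residual_rate for s in config.species.rows}

    # (1) diffusion: species ascending, then informant polymers, then boxes
    diffuse_all_species(state, rates, rng)
    diffuse_polymers(state, config.species.polymer1_residual_rate, rng)
    diffuse_boxes2(state, config.species.polymer2_residual_rate, rng)

    # (2) reaction network with energy truncation
    counts = state.counts_view()
    ledger.reaction_events = int(apply_network(counts, config.network, rng).sum())

    # (3) polymerisation / decomposition
    ledger.boxes_formed = form_boxes(state, config.triggers, rng)
    ledger.boxes_decomposed = decompose_boxes(state, config.triggers, rng)
    ledger.polymers_decayed = decay_polymers1(state, config.triggers, rng)

    # (4) replication + mutation
    ledger.polymers_created = replicate_polymers1(state, config.params, rng)
    mutate_residents(state, config.params, rng)

    # (5) catalysed energy production, (6) waste removal, (7) supply
    ledger.energy_produced = produce_energy(state, rng)
    ledger.waste_removed = remove_waste(state)
    ledger.resource_supplied = supply_resource(
        state, scheduled_E(config.energy, state.step + 1)
    )

    state.step += 1
    return ledger


def detect_survival(occupied: Sequence[int], horizon: int | None = None) -> tuple[str, int | None]:
    """Classify a per-step series of box-occupied cell counts.

    Extinct iff the count *falls* to zero — i.e. reaches zero at some step
    after having been positive — before the horizon; otherwise survived.
    (A prefix of a surviving series therefore never classifies as extinct.)
    Returns ``(outcome, extinction_step)``.
    """
    occ = list(occupied if horizon is None else occupied[:horizon])
    emerged_at = next((i for i, v in enumerate(occ) if v > 0), None)
    if emerged_at is None:
        return SURVIVED, None
    for i in range(emerged_at + 1, len(occ)):
        if occ[i] == 0:
            return EXTINCT, i
    return SURVIVED, None


_SERIES_COLUMNS = (
    ["step"]
    + [f"mol{sid}" for sid in MOLECULE_IDS]
    + [
        "polymer1_count",
        "mean_catalytic_ratio",
        "polymer2_boxes",
        "occupied_cells",
        "polymers_created",
        "polymers_decayed",
        "boxes_formed",
        "boxes_decomposed",
        "reaction_events",
        "energy_produced",
        "waste_removed",
        "resource_supplied",
    ]
)


def run_trial(config: TrialConfig, keep_state: bool = False) -> TrialResult:
    """Initialise and run one trial to ``max_steps`` or extinction.

    Deterministic given (config, seed).  The recorded series has one row per
    executed step; extinction stops the loop at the step where the boundary
    region vanishes.
    """
    config = config.resolved()
    rng = np.random.default_rng(config.seed)
    state = initialize(config, rng)
    rows: list[list] = []
    emerged = False
    outcome, ext_step = SURVIVED, None
    for _ in range(config.max_steps):
        ledger = step(state, config, rng)
        occ = state.occupied_box_cells()
        totals = state.counts.sum(axis=(1, 2))
        pop = state.polymers
        rows.append(
            [state.step]
            + [int(t) for t in totals]
            + [
                len(pop),
                pop.mean_ratio(),
                int(state.boxes2.sum()),
                occ,
                ledger.polymers_created,
                ledger.polymers_decayed,
                ledger.boxes_formed,
                ledger.boxes_decomposed,
                ledger.reaction_events,
                ledger.energy_produced,
                ledger.waste_removed,
                ledger.resource_supplied,
            ]
        )
        if occ > 0:
            emerged = True
        elif emerged:
            outcome, ext_step = EXTINCT, state.step
            break
    series = pd.DataFrame(rows, columns=_SERIES_COLUMNS)
    final_ratio = (
        float(series["mean_catalytic_ratio"].iloc[-1]) if len(series) else float("nan")
    )
    return TrialResult(
        series=series,
        outcome=outcome,
        extinction_step=ext_step,
        seed=config.seed,
        final_mean_ratio=final_ratio,
        final_state=state if keep_state else None,
    )


def sweep(
    base: TrialConfig,
    E_values: Iterable[int] | None = None,
    m_values: Iterable[float] | None = None,
    n_trials: int = 10,
) -> pd.DataFrame:
    """Replicate trials over an energy-supply grid and/or a mutation-rate
    grid.  Trial ``i`` of every setting uses seed ``base.seed + i`` (settings
    differ only by random stream).  Returns a tidy table with one row per
    trial."""
    settings: list[tuple[str, float]] = []
    for E in E_values or ():
        settings.append(("E", int(E)))
    for m in m_values or ():
        settings.append(("mutation_rate", float(m)))
    if not settings:
        settings = [("E", scheduled_E(base.energy, 0))]
    rows = []
    for name, value in settings:
        for i in range(n_trials):
            cfg = replace(base, seed=base.seed + i)
            if name == "E":
                cfg = replace(cfg, energy=EnergySchedule.constant(int(value)))
            else:
                cfg = replace(cfg, params=replace(base.params, mutation_rate=value))
            res = run_trial(cfg)
            rows.append(
                {
                    "parameter": name,
                    "value": value,
                    "trial": i,
                    "seed": cfg.seed,
                    "outcome": res.outcome,
                    "survived": res.survived,
                    "extinction_step": res.extinction_step,
                    "final_mean_ratio": res.final_mean_ratio,
                    "final_occupied_cells": (
                        int(res.series["occupied_cells"].iloc[-1]) if len(res.series) else 0
                    ),
                }
            )
    return pd.DataFrame(rows)
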