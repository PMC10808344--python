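"""Lattice state: per-cell integer multisets plus polymer instances."""

from __future__ import annotations

import numpy as np

from .grid import HexGrid
from .polymers import Polymer1Population, PolymerInstance, POLYMER_LENGTH
from .species import BOUNDARY_MONOMER, MOLECULE_IDS


class LatticeState:
    """Complete simulation state at one time step.

    ``counts`` is an ``(n_species, H, W)`` int64 array of free-molecule
    counts (species in :data:`~hexchem.species.MOLECULE_IDS` order);
    ``polymers`` holds the informant-polymer instances; ``boxes2`` counts
    boundary boxes per cell (boundary polymers carry no sequence information,
    so a count is a complete representation).  Counts are never negative and
    change only through reactions, supply or waste removal — diffusion merely
    relocates them.
    """

    def __init__(self, grid: HexGrid, species_ids: tuple[int, ...] = MOLECULE_IDS):
        self.grid = grid
        self.species_ids = tuple(species_ids)
        self._index = {sid: i for i, sid in enumerate(self.species_ids)}
        self.counts = np.zeros((len(self.species_ids), grid.height, grid.width), dtype=np.int64)
        self.boxes2 = np.zeros((grid.height, grid.width), dtype=np.int64)
        self.polymers = Polymer1Population()
        self.step = 0
        self._views: dict[int, np.ndarray] | None = None

    def counts_view(self) -> dict[int, np.ndarray]:
        """Mapping species id -> (H, W) int64 view into ``counts`` (shared
        memory; mutate in place)."""
        if self._views is None:
            self._views = {sid: self.counts[i] for sid, i in self._index.items()}
        return self._views

    def species_index(self, species_id: int) -> int:
        try:
            return self._index[species_id]
        except KeyError:
            raise KeyError(f"unknown species {species_id}") from None

    def total_count(self, species_id: int) -> int:
        """Lattice-wide total of one species' free molecules."""
        return int(self.counts[self.species_index(species_id)].sum())

    def totals(self) -> dict[int, int]:
        sums = self.counts.sum(axis=(1, 2))
        return {sid: int(sums[i]) for sid, i in self._index.items()}

    def boundary_monomer_mass(self) -> int:
        """Free molecule 12 plus monomers locked in boundary boxes."""
        return self.total_count(BOUNDARY_MONOMER) + POLYMER_LENGTH * int(self.boxes2.sum())

    def occupied_box_cells(self) -> int:
        """Number of cells holding at least one full boundary box — the
        survival observable."""
        return int((self.boxes2 > 0).sum())

    def polymers_in(self, cell: int) -> list[PolymerInstance]:
        """API-level view: polymer instances resident in one cell (boundary
        boxes included as identical full instances)."""
        out = self.polymers.instances_in(cell)
        r, c = self.grid.rowcol(cell)
        out += [
            PolymerInstance(2, (BOUNDARY_MONOMER,) * POLYMER_LENGTH)
            for _ in range(int(self.boxes2[r, c]))
        ]
        return out

    def copy(self) -> "LatticeState":
        out = LatticeState(self.grid, self.species_ids)
        out.counts = self.counts.copy()
        out.boxes2 = self.boxes2.copy()
        out.polymers = self.polymers.copy()
        out.step = self.step
        return out

    def validate(self) -> None:
        if (self.counts < 0).any() or (self.boxes2 < 0).any():
            raise ValueError("negative count in lattice state")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LatticeState(step={self.step}, {self.grid!r}, "
            f"polymers={len(self.polymers)}, boxes={int(self.boxes2.sum())})"
        )
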