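"""Molecular species and their standard parameters.

Eighteen monomeric species are tracked as integer counts per lattice cell:
molecules 1-15 form the cyclic reaction network, molecule 20 is the energy
resource, molecule 25 the energy carrier and molecule 19 the spent-energy
waste.  Two polymer types (length-100 chains) are carried separately by the
lattice state; only their diffusion residual rates live here.

Each species has a *residual rate* ``r``: the fraction of its molecules that
stay in their cell during one diffusion step (``r = 1`` means immobile,
``r = 0`` means everything scatters to the six neighbours each step).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

#: Canonical species identifiers, ascending.  Also the diffusion draw order.
MOLECULE_IDS: tuple[int, ...] = tuple(range(1, 16)) + (19, 20, 25)

WASTE = 19      #: spent energy carrier, removed from the lattice each step
RESOURCE = 20   #: energy resource, re-supplied where exhausted
ENERGY = 25     #: energy carrier consumed by network reactions
MONOMER_A = 6   #: informant-polymer monomer carrying the catalytic motif
MONOMER_B = 7   #: informant-polymer monomer, inert in the motif
BOUNDARY_MONOMER = 12  #: boundary-polymer feedstock
REPLICATION_TRIGGER = 11  #: its presence enables informant replication


@dataclass(frozen=True)
class Species:
    """One row of the species table."""

    species_id: int
    residual_rate: float
    initial_global: int = 0
    #: count per cell inside the central seed area; ``None`` means the global
    #: value applies there too.
    initial_central: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.residual_rate <= 1.0:
            raise ValueError(
                f"species {self.species_id}: residual rate "
                f"{self.residual_rate} outside [0, 1]"
            )
        if self.initial_global < 0 or (
            self.initial_central is not None and self.initial_central < 0
        ):
            raise ValueError(f"species {self.species_id}: negative initial count")


@dataclass(frozen=True)
class SpeciesTable:
    """Standard per-species parameters: residual rates and initial counts.

    Covers the 18 molecular species plus the two polymer types (whole chains
    diffuse as units with their own residual rates; the informant polymer is
    additionally seeded as ``polymer1_initial_central`` instances in the
    central area).
    """

    rows: tuple[Species, ...] = field(default_factory=lambda: _STANDARD_ROWS)
    polymer1_residual_rate: float = 0.75
    polymer2_residual_rate: float = 0.75
    polymer1_initial_central: int = 10

    def __post_init__(self):
        ids = [s.species_id for s in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species id in table")
        if set(ids) != set(MOLECULE_IDS):
            missing = set(MOLECULE_IDS) - set(ids)
            extra = set(ids) - set(MOLECULE_IDS)
            raise ValueError(
                f"species table must contain exactly {MOLECULE_IDS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for r in (self.polymer1_residual_rate, self.polymer2_residual_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"polymer residual rate {r} outside [0, 1]")
        if self.polymer1_initial_central < 0:
            raise ValueError("negative initial polymer count")

    def __getitem__(self, species_id: int) -> Species:
        for s in self.rows:
            if s.species_id == species_id:
                return s
        raise KeyError(f"unknown species {species_id}")

    def residual_rate(self, species_id: int) -> float:
        return self[species_id].residual_rate

    def with_row(self, **kwargs) -> "SpeciesTable":
        """Return a copy with one species row replaced (test convenience)."""
        sid = kwargs["species_id"]
        rows = tuple(
            replace(s, **kwargs) if s.species_id == sid else s for s in self.rows
        )
        return replace(self, rows=rows)


# Standard parameter set.  Molecules 4 and 5 share molecule 2's residual
# rate; bookkeeping molecules 8-11 and 13-15 are immobile (r = 1) so that
# the transition state of a cell stays local.
_STANDARD_ROWS: tuple[Species, ...] = (
    Species(1, 0.0, 1_000_000),
    Species(2, 0.75, 0, 100),
    Species(3, 0.05, 0, 100),
    Species(4, 0.75),
    Species(5, 0.75),
    Species(6, 0.0, 50_000),
    Species(7, 0.0, 50_000),
    Species(8, 1.0),
    Species(9, 1.0),
    Species(10, 1.0),
    Species(11, 1.0),
    Species(12, 0.0, 100_000),
    Species(13, 1.0),
    Species(14, 1.0, 0, 3),
    Species(15, 1.0, 0, 9),
    Species(19, 0.0),
    Species(20, 0.4, 100, 1000),
    Species(25, 0.2, 100, 500),
)


def standard_species_table() -> SpeciesTable:
    """The standard-case species table (fresh instance)."""
    return SpeciesTable()
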