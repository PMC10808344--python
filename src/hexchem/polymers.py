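"""Virtual-box polymers: sequences, motif statistics, mutation, replication.

Two polymer types exist, both chains of 100 monomers held in "virtual boxes"
that diffuse through the lattice as units:

* **informant** (type 1): monomers from molecules {6, 7}.  The arrangement of
  molecule 6 carries heritable information — runs of five consecutive
  molecule-6 monomers act as the catalytic motif for energy production.
* **boundary** (type 2): 100 copies of molecule 12.  Aggregations of these
  boxes form the cell-like region whose persistence defines survival.

Filling a box with free monomers models polymerisation; emptying it returns
the monomers, so free + boxed monomer mass is conserved by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._util import stochastic_round
from .species import BOUNDARY_MONOMER, MONOMER_A, MONOMER_B, REPLICATION_TRIGGER

POLYMER_LENGTH = 100  #: box capacity: a full polymer is exactly 100 monomers
MOTIF_LENGTH = 5      #: catalytic motif = this many consecutive molecule 6

#: Serialisation alphabet for sequence snapshots.
SEQ_ALPHABET: Mapping[int, str] = {MONOMER_A: "A", MONOMER_B: "B", BOUNDARY_MONOMER: "M"}
_SEQ_REVERSE = {v: k for k, v in SEQ_ALPHABET.items()}


@dataclass(frozen=True)
class PolymerParams:
    """Informant-polymer parameters.

    ``w`` is the morphology parameter: the molecule-6 composition ratio
    ``n6 / (n6 + n7)``; 0.68 is the standard value at which the underlying
    reaction network supports dividing cell-like regions.  ``mutation_rate``
    is the probability that a freshly replicated copy undergoes one random
    6<->7 positional swap (composition-preserving).  ``resident_mutation_p``
    optionally applies the same swap to every resident polymer each step
    (0 disables it; replication-time mutation is the standard setting).
    """

    w: float = 0.68
    mutation_rate: float = 0.1
    motif_length: int = MOTIF_LENGTH
    resident_mutation_p: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"composition ratio w={self.w} outside [0, 1]")
        for name in ("mutation_rate", "resident_mutation_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PolymerTriggers:
    """Rule-driven triggers wiring boxes to the reaction network.

    Boundary-box formation fires where the bookkeeping trigger molecule
    (13 by default) is present, converting 100 free molecule 12 into one full
    box with probability ``formation_p`` per formable box per step.  Boxes
    and informant polymers decompose spontaneously with small per-step
    probabilities, returning their monomers to the free pool.
    """

    formation_catalyst: int | None = 13
    formation_p: float = 0.2
    box_decay_p: float = 0.01
    polymer1_decay_p: float = 0.01

    def __post_init__(self):
        for name in ("formation_p", "box_decay_p", "polymer1_decay_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PolymerInstance:
    """A single polymer: an ordered monomer sequence in a virtual box."""

    ptype: int  # 1 = informant, 2 = boundary
    sequence: tuple[int, ...]
    capacity: int = POLYMER_LENGTH

    def __post_init__(self):
        if self.ptype not in (1, 2):
            raise ValueError(f"unknown polymer type {self.ptype}")
        if len(self.sequence) > self.capacity:
            raise ValueError("sequence exceeds box capacity")
        allowed = {MONOMER_A, MONOMER_B} if self.ptype == 1 else {BOUNDARY_MONOMER}
        if not set(self.sequence) <= allowed:
            raise ValueError(f"monomers outside {sorted(allowed)} in type-{self.ptype} polymer")

    @property
    def full(self) -> bool:
        return len(self.sequence) == self.capacity


def _check_informant(seq: np.ndarray) -> np.ndarray:
    seq = np.asarray(seq)
    bad = ~np.isin(seq, (MONOMER_A, MONOMER_B))
    if bad.any():
        raise ValueError(f"non-{{6,7}} monomer in informant sequence: {seq[bad][:5]}")
    return seq


def random_polymer1(w: float, rng: np.random.Generator, length: int = POLYMER_LENGTH) -> np.ndarray:
    """Uniformly shuffled informant sequence with exactly ``round(length*w)``
    molecule-6 monomers (the initial-arrangement procedure)."""
    n6 = int(round(length * w))
    seq = np.full(length, MONOMER_B, dtype=np.uint8)
    seq[:n6] = MONOMER_A
    rng.shuffle(seq)
    return seq


def catalytic_ratio(sequence) -> float:
    """Composition ratio of five-consecutive molecule 6.

    Counts overlapping length-5 windows made entirely of molecule 6 and
    divides by the number of molecule-6 monomers in the sequence (0 when the
    sequence has no molecule 6).  For a uniformly shuffled 68:32 length-100
    sequence the ensemble mean is ~0.19, matching the neutral baseline this
    statistic is calibrated against.
    """
    seq = _check_informant(sequence)
    is6 = (seq == MONOMER_A).astype(np.int64)
    n6 = int(is6.sum())
    if n6 == 0 or len(seq) < MOTIF_LENGTH:
        return 0.0
    windows = np.convolve(is6, np.ones(MOTIF_LENGTH, dtype=np.int64), mode="valid")
    return float((windows == MOTIF_LENGTH).sum() / n6)


def catalytic_ratios(seqs: np.ndarray) -> np.ndarray:
    """Vectorised :func:`catalytic_ratio` over an ``(n, length)`` batch."""
    seqs = np.atleast_2d(np.asarray(seqs))
    is6 = (seqs == MONOMER_A).astype(np.int64)
    n6 = is6.sum(axis=1)
    if seqs.shape[1] < MOTIF_LENGTH:
        return np.zeros(len(seqs))
    sw = np.lib.stride_tricks.sliding_window_view(is6, MOTIF_LENGTH, axis=1)
    wins = (sw.sum(axis=2) == MOTIF_LENGTH).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n6 > 0, wins / np.maximum(n6, 1), 0.0)
    return out


def run_length_profile(sequence) -> dict[int, int]:
    """Counts of maximal molecule-6 runs keyed by run length.

    ``sum(length * count)`` over the profile equals the number of molecule-6
    monomers in the sequence.
    """
    seq = _check_informant(sequence)
    profile: dict[int, int] = {}
    run = 0
    for m in seq:
        if m == MONOMER_A:
            run += 1
        elif run:
            profile[run] = profile.get(run, 0) + 1
            run = 0
    if run:
        profile[run] = profile.get(run, 0) + 1
    return profile


def mutate(sequence, m: float, rng: np.random.Generator) -> np.ndarray:
    """With probability ``m``, swap one uniformly chosen molecule-6 position
    with one uniformly chosen molecule-7 position; otherwise return the
    sequence unchanged.  Composition is preserved exactly; sequences lacking
    either monomer are degenerate fixed points."""
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"mutation rate {m} outside [0, 1]")
    seq = np.array(_check_informant(sequence), dtype=np.uint8)
    if rng.random() >= m:
        return seq
    pos6 = np.flatnonzero(seq == MONOMER_A)
    pos7 = np.flatnonzero(seq == MONOMER_B)
    if len(pos6) == 0 or len(pos7) == 0:
        return seq
    i = rng.integers(len(pos6))
    j = rng.integers(len(pos7))
    seq[pos6[i]], seq[pos7[j]] = MONOMER_B, MONOMER_A
    return seq


def seq_to_str(seq) -> str:
    return "".join(SEQ_ALPHABET[int(m)] for m in seq)


def str_to_seq(s: str) -> np.ndarray:
    return np.array([_SEQ_REVERSE[c] for c in s], dtype=np.uint8)


class Polymer1Population:
    """Struct-of-arrays store for all informant-polymer instances on a
    lattice: home cell (flat index), sequence, and a cached catalytic ratio
    per instance.  Sequences are immutable once added, so the cache is
    computed exactly once per instance."""

    def __init__(self, length: int = POLYMER_LENGTH):
        self.length = length
        self.cells = np.empty(0, dtype=np.int64)
        self.seqs = np.empty((0, length), dtype=np.uint8)
        self.ratios = np.empty(0, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.cells)

    def add(self, cells, seqs) -> None:
        cells = np.atleast_1d(np.asarray(cells, dtype=np.int64))
        seqs = np.atleast_2d(np.asarray(seqs, dtype=np.uint8))
        if len(cells) != len(seqs):
            raise ValueError("cells/seqs length mismatch")
        self.cells = np.concatenate([self.cells, cells])
        self.seqs = np.concatenate([self.seqs, seqs])
        self.ratios = np.concatenate([self.ratios, catalytic_ratios(seqs)])

    def remove(self, mask: np.ndarray) -> None:
        keep = ~np.asarray(mask, dtype=bool)
        self.cells = self.cells[keep]
        self.seqs = self.seqs[keep]
        self.ratios = self.ratios[keep]

    def counts_per_cell(self, n_cells: int) -> np.ndarray:
        return np.bincount(self.cells, minlength=n_cells)

    def mean_ratio_per_cell(self, n_cells: int) -> np.ndarray:
        """Per-cell arithmetic mean of resident catalytic ratios (0 where no
        polymer is resident)."""
        cnt = np.bincount(self.cells, minlength=n_cells)
        tot = np.bincount(self.cells, weights=self.ratios, minlength=n_cells)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)

    def monomer_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-instance (n6, n7) counts."""
        is6 = self.seqs == MONOMER_A
        n6 = is6.sum(axis=1).astype(np.int64)
        return n6, self.seqs.shape[1] - n6

    def mean_ratio(self) -> float:
        return float(self.ratios.mean()) if len(self) else float("nan")

    def instances_in(self, cell: int) -> list[PolymerInstance]:
        return [
            PolymerInstance(1, tuple(int(x) for x in self.seqs[i]))
            for i in np.flatnonzero(self.cells == cell)
        ]

    def copy(self) -> "Polymer1Population":
        out = Polymer1Population(self.length)
        out.cells = self.cells.copy()
        out.seqs = self.seqs.copy()
        out.ratios = self.ratios.copy()
        return out


# ---------------------------------------------------------------------------
# Lattice-level polymer operators (engine side).  These take the simulation
# state duck-typed: ``state.counts_view()`` mapping species -> (H, W) int64,
# ``state.polymers`` a Polymer1Population, ``state.boxes2`` an (H, W) int64
# box-count array.
# ---------------------------------------------------------------------------


def form_boxes(state, triggers: PolymerTriggers, rng: np.random.Generator) -> int:
    """Polymerise free molecule 12 into boundary boxes where the formation
    trigger is present.  Each formable box (100 free monomers, one trigger
    molecule) fills with probability ``formation_p``."""
    counts = state.counts_view()
    free12 = counts[BOUNDARY_MONOMER]
    formable = free12 // POLYMER_LENGTH
    if triggers.formation_catalyst is not None:
        formable = np.minimum(formable, counts[triggers.formation_catalyst])
    formed = np.minimum(stochastic_round(formable * triggers.formation_p, rng), formable)
    free12 -= POLYMER_LENGTH * formed
    state.boxes2 += formed
    return int(formed.sum())


def decompose_boxes(state, triggers: PolymerTriggers, rng: np.random.Generator) -> int:
    """Spontaneously empty boundary boxes, returning 100 molecule 12 each."""
    dec = rng.binomial(state.boxes2, triggers.box_decay_p)
    state.boxes2 -= dec
    state.counts_view()[BOUNDARY_MONOMER] += POLYMER_LENGTH * dec
    return int(dec.sum())


def decay_polymers1(state, triggers: PolymerTriggers, rng: np.random.Generator) -> int:
    """Spontaneously decompose informant polymers, returning their monomers
    to the free 6/7 pools of their home cells."""
    pop: Polymer1Population = state.polymers
    if len(pop) == 0:
        return 0
    mask = rng.random(len(pop)) < triggers.polymer1_decay_p
    if mask.any():
        n6, n7 = pop.monomer_counts()
        counts = state.counts_view()
        np.add.at(counts[MONOMER_A].ravel(), pop.cells[mask], n6[mask])
        np.add.at(counts[MONOMER_B].ravel(), pop.cells[mask], n7[mask])
        pop.remove(mask)
    return int(mask.sum())


def replicate_polymers1(state, params: PolymerParams, rng: np.random.Generator) -> int:
    """Template replication of informant polymers.

    In every cell that (a) holds at least one molecule 11, (b) hosts at least
    one informant polymer and (c) has free molecule 6 and 7 pools at least as
    large as a resident template's own composition, one uniformly chosen
    resident template is copied: the copy consumes exactly the template's
    monomer counts from the free pools and then undergoes the mutation step
    with probability ``params.mutation_rate``.  Molecule 11 acts as a
    catalyst (required present, not consumed).  At most one copy per cell per
    step.
    """
    pop: Polymer1Population = state.polymers
    n = len(pop)
    if n == 0:
        return 0
    counts = state.counts_view()
    c11 = counts[REPLICATION_TRIGGER].ravel()
    free6 = counts[MONOMER_A].ravel()
    free7 = counts[MONOMER_B].ravel()

    # one uniformly random resident template per occupied cell
    perm = rng.permutation(n)
    cells_p = pop.cells[perm]
    uniq_cells, first = np.unique(cells_p, return_index=True)
    template_idx = perm[first]

    n6_t = (pop.seqs[template_idx] == MONOMER_A).sum(axis=1).astype(np.int64)
    n7_t = pop.seqs.shape[1] - n6_t
    ok = (c11[uniq_cells] >= 1) & (free6[uniq_cells] >= n6_t) & (free7[uniq_cells] >= n7_t)
    if not ok.any():
        return 0
    cells_new = uniq_cells[ok]
    copies = pop.seqs[template_idx[ok]].copy()
    free6[cells_new] -= n6_t[ok]
    free7[cells_new] -= n7_t[ok]

    _mutate_batch(copies, params.mutation_rate, rng)
    pop.add(cells_new, copies)
    return len(cells_new)


def mutate_residents(state, params: PolymerParams, rng: np.random.Generator) -> int:
    """Optional per-step mutation of resident polymers (off by default)."""
    if params.resident_mutation_p <= 0 or len(state.polymers) == 0:
        return 0
    pop = state.polymers
    seqs = pop.seqs.copy()
    k = _mutate_batch(seqs, params.resident_mutation_p, rng)
    if k:
        pop.seqs = seqs
        pop.ratios = catalytic_ratios(seqs)
    return k


def _mutate_batch(seqs: np.ndarray, m: float, rng: np.random.Generator) -> int:
    """In-place: each row independently undergoes one random 6<->7 swap with
    probability ``m``.  Returns the number of rows mutated.  Matches the
    single-sequence :func:`mutate` semantics draw-for-draw at the row level."""
    k = len(seqs)
    if k == 0:
        return 0
    hit = rng.random(k) < m
    idx = np.flatnonzero(hit)
    if len(idx) == 0:
        return 0
    sub = seqs[idx]
    is6 = sub == MONOMER_A
    n6 = is6.sum(axis=1)
    n7 = sub.shape[1] - n6
    viable = (n6 > 0) & (n7 > 0)
    # uniform target ordinals among the 6s and the 7s of each row
    k6 = (rng.random(len(idx)) * n6).astype(np.int64)
    k7 = (rng.random(len(idx)) * n7).astype(np.int64)
    cs6 = np.cumsum(is6, axis=1)
    cs7 = np.cumsum(~is6, axis=1)
    p6 = np.argmax(is6 & (cs6 == (k6 + 1)[:, None]), axis=1)
    p7 = np.argmax(~is6 & (cs7 == (k7 + 1)[:, None]), axis=1)
    rows = np.arange(len(idx))[viable]
    sub[rows, p6[viable]] = MONOMER_B
    sub[rows, p7[viable]] = MONOMER_A
    seqs[idx] = sub
    return int(viable.sum())


def box_from_monomers(counts: dict[int, int]) -> PolymerInstance:
    """API-level formation: build one full boundary box from a free-count
    mapping, consuming 100 molecule 12.  Raises if insufficient."""
    if counts.get(BOUNDARY_MONOMER, 0) < POLYMER_LENGTH:
        raise ValueError("insufficient free molecule 12 to fill a box")
    counts[BOUNDARY_MONOMER] -= POLYMER_LENGTH
    return PolymerInstance(2, (BOUNDARY_MONOMER,) * POLYMER_LENGTH)


def decompose_box(instance: PolymerInstance, counts: dict[int, int]) -> None:
    """API-level decomposition: return a box's monomers to a free-count
    mapping (inverse of :func:`box_from_monomers` / replication)."""
    for m in instance.sequence:
        counts[int(m)] = counts.get(int(m), 0) + 1
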