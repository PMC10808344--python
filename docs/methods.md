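# Methods

## Model

`hexchem` simulates an artificial chemistry on a toroidal hexagonal lattice
(default 100×100 cells).  The state of a cell at integer time *t* is an
integer multiset over 18 molecular species (ids 1–15, 19, 20, 25) plus a
list of resident polymer instances.  One synchronous step applies, in this
order:

1. **diffusion** of every species (ascending id), then informant polymers,
   then boundary boxes;
2. **reactions** — the multiset-rewriting network, with energy truncation;
3. **polymerisation** — boundary-box formation and decomposition, informant
   decay;
4. **replication** of informant polymers, with mutation;
5. **energy production** (catalysed 20 → 25);
6. **waste removal** (molecule 19 cleared);
7. **resource supply** (quantum *E* to cells whose molecule-20 stock is 0).

A single PCG64 stream seeded per trial drives every draw in a fixed
documented order, so one (configuration, seed) pair is bit-reproducible
across processes.

### Lattice topology

Cells are addressed on a rectangular array with axial (rhombic) hexagonal
adjacency: the six neighbour offsets (±1 column, ±1 row, and the two mixed
diagonals) are the same for every cell, so the scheme is parity-free, wraps
consistently on a torus of any dimensions ≥ 3, and the neighbour relation is
symmetric and 6-regular everywhere.  We chose this over row-parity ("offset")
schemes because those require even dimensions under periodic wrap, which
would exclude the small odd-sized lattices used by the diffusion oracle
tests.  At dimension 2 opposite neighbours coincide, so such grids are
rejected.

### Diffusion and integer rounding

The residual rate *r* per species is the fraction of molecules that stay
put.  From a cell holding *b* molecules, `⌊b·r⌋` stay, each neighbour
receives `⌊b(1−r)/6⌋`, and the remaining `b − ⌊b·r⌋ − 6⌊b(1−r)/6⌋`
molecules (at most six) each go to one uniformly random neighbour.
Rounding down keeps all counts integral and non-negative; the fractional
part of the *residual* share is deliberately assigned to the movers rather
than to the stayers (an unspecified corner of the update rule; keeping
leftovers mobile avoids a systematic immobilising bias for slow species).
A consequence worth knowing: the operator is a variance-reduced version of
moving each molecule independently.  Its expectation matches the
per-molecule model exactly whenever `b·r` is integral, and its full
distribution matches when the deterministic shares vanish (`r = 0`,
`b < 6`); the test suite checks both regimes.  Floor operations add a
`1e-9` guard so products like `600 × 0.75` cannot land one ulp below an
integer.

### Reactions

A rule converts its reactant multiset into its product multiset with
probability *p* per candidate event; the candidate count in a cell is
`min_s ⌊count_s / multiplicity_s⌋` over reactants, and the realised event
count is the stochastic rounding of `candidates × p` (floor plus one
Bernoulli trial on the fraction), reproducing the mean-field update
`A(t+1) = A(t)(1−p)` without leaving the integers.  Rules fire sequentially
in listed order on live counts: order is part of the configuration, makes
over-spending structurally impossible, and — because energy-costing rules
draw on the live molecule-25 stock — doubles as the energy priority under
scarcity.  Catalysts are required present but not consumed; writing a
catalyst on both sides of a rule instead makes the event count proportional
to its abundance (the `a + b ⇒ a + c` pattern).

### The default network

The engine is rule-agnostic; the network is data (`networks/default.yaml`).
The bundled default satisfies the structural constraints of the modelled
chemistry — fifteen species, cyclic decay back to feedstock molecule 1,
exact count conservation, catalyst-conditioned steps — and wires the
following roles: molecules 2/3 are a slow/fast-diffusing
activator/inhibitor pair (residual rates 0.75/0.05) with energy-costing
autocatalysis and free decay; 4/5 are their spent forms; 8→9→10→11 is the
cascade whose product 11 enables replication; 13 (decaying through 14/15)
triggers boundary-box formation.  The individual rate constants are not
dictated by the modelled chemistry; they are tuning parameters calibrated
once against the qualitative behaviours the model must show — emergence
and spread of a boundary region at E = 800, collapse to extinction at
E = 0, viability at E ≥ 500 — and then frozen.  Qualitative behaviour, not
stoichiometric identity with any particular published rule set, is the
validation surface.

### Polymers, replication, mutation

Polymers are "virtual boxes" of capacity 100 that diffuse as units
(residual rate 0.75).  Boundary boxes (100 × molecule 12) are mutually
identical, so the engine stores them as a per-cell count; informant
polymers carry their sequences.  Box formation converts 100 free molecule
12 into one box where trigger molecule 13 is present (probability 0.2 per
formable box per step); boxes and informant polymers decay spontaneously
(probability 0.01 per instance per step), returning their monomers.  Free +
boxed monomer mass is conserved by construction.

Replication fires in any cell holding ≥ 1 molecule 11, at least one
resident informant, and free molecule-6/7 pools covering the template's own
composition; one uniformly chosen resident template is copied per cell per
step, consuming exactly its composition from the free pools.  Molecule 11
is treated as a catalyst (required, not consumed) — the alternative
(consumption) is a flagged unknown; presence-only is the minimal reading.
With probability *m* (default 0.1) the copy undergoes one uniformly chosen
6↔7 positional swap.  Composition is preserved exactly, so the morphology
parameter *w* is heritable and only the *arrangement* evolves.  Repeated
swapping is a Markov chain whose stationary law is uniform over
arrangements of fixed composition; the tests verify relaxation to the
shuffle ensemble.

### The catalytic motif statistic

The five-consecutive composition ratio of a sequence is the number of
overlapping length-5 windows consisting entirely of molecule 6, divided by
the number of molecule-6 monomers (0 when none).  Among candidate
formalisations of "ratio of five-consecutive molecule 6", this is the one
whose neutral ensemble mean at 68:32, length 100, is ≈ 0.19 — analytically
`96 × (68)₅/(100)₅ / 68 ≈ 0.1955`, confirmed by Monte-Carlo in the
acceptance suite — matching the baseline the energy map is anchored to.
The definition is isolated in one function (`catalytic_ratio`) so it can be
swapped.

### Energy metabolism

Production 20 → 25 fires only in cells hosting ≥ 1 informant polymer, with
per-step, per-molecule probability `clamp(4.0·c − 0.6, 0, 1)`, where *c*
aggregates the cell's residents as the arithmetic mean of per-instance
ratios (the simplest consistent reading of rate-set-by-catalyst-content;
clamping is forced below 0.15 by the formula going negative and above 0.4
by probability semantics).  Every energy-costing reaction event converts
one molecule 25 to waste 19; waste is cleared at the end of each step (it
is created mid-step and never diffuses, so no separate ordering switch is
needed).  Supply adds *E* molecules 20 to every cell whose stock is exactly
0 at the end of a step.  Schedules are piecewise constant; an entry
`(from_step, E)` takes effect from `from_step + 1`, so "reduced after step
4000" leaves step 4000 at the old value.

### Survival and selection

The survival observable is the number of cells holding at least one
boundary box.  A trial is **extinct** when that count *falls* to zero —
reaches zero after having been positive — and **survived** otherwise; a
series in which boxes never appear records no extinction event (this
keeps the classification monotone under truncation, and in practice boxes
always form within the first steps from the seeded central energy stock).

Selection needs no dedicated machinery: cells whose informants average
below c = 0.15 produce no energy, their bookkeeping cascades stall,
replication stops, and their polymers and boxes decay away, while
higher-motif neighbourhoods keep replicating.  In calibration runs the
population-mean ratio of surviving trials ends in the 0.23–0.40 range,
well above the 0.19 neutral baseline, including under low or decreasing
energy supply — adaptation by enrichment of high-motif lineages.

## Standard parameters

Per-species residual rates and initial counts (standard case): molecule 1 —
r = 0, 10⁶ per cell; 2 — r = 0.75, 100 in the central area; 3 — r = 0.05,
100 central; 4/5 — r = 0.75; 6/7 — r = 0, 50 000 per cell; 8–11 — r = 1;
12 — r = 0, 100 000 per cell; 13 — r = 1; 14/15 — r = 1, 3 and 9 central;
19 — r = 0; 20 — r = 0.4, 100 per cell, 1000 central; 25 — r = 0.2, 100 per
cell, 500 central; both polymer types — r = 0.75.  The central area is a
hex disk of radius 3 (37 cells) around the lattice centre — the seed
footprint has no uniquely right shape, so its geometry is a config knob
(`central_radius`) — and receives ten informant polymers
generated at w = 0.68, placed round-robin over the innermost cells.
Experiment defaults: E = 800 (sweep grid 200–800), mutation rate 0.1
(sweep grid 0.1–0.5), horizon 8000 steps; replicate *i* of a sweep uses
seed `base + i`, settings differing only by random stream.

## Problem sizes

The full standard case (100×100, 8000 steps) runs in tens of minutes.  The
packaged quantitative checks use scaled-down conditions chosen to preserve
the phenomena: 50×50 lattices over 2000 steps for the energy-sweep
selection checks (the boundary region and its collapse dynamics are local,
so halving the linear size leaves them intact), 20×20–30×30 for the
starvation, emergence and trend checks.  The neutral-baseline ensemble
uses 50 000 shuffles (standard error ≈ 4×10⁻⁴).

## Known limitations

* The default network is a reconstruction constrained by structure and
  qualitative behaviour; quantitative trajectories (survival counts per 10
  trials at each E, pictorial morphologies) are not reproduction targets.
* At test scales the E-survival relation saturates: small lattices with
  well-mixed monomer pools let populations adapt their motif content
  quickly, so even E = 100–200 trials often survive by evolving c ≈ 0.4.
  The ensemble assertion is therefore a one-sided trend (survival count
  non-decreasing in E), not a fixed dose–response curve.
* Boundary-box formation/decomposition triggers are minimal (catalyst-gated
  formation, spontaneous decay); the decay-side bookkeeping species 14/15
  participate only as decay products of 13.
* Mutation is attached to replication only by default; per-step resident
  mutation exists behind `resident_mutation_p` but is off.
* No spatially heterogeneous resource fields, no square-grid or
  non-periodic modes, no exact-SSA (Gillespie) semantics — the update is
  synchronous per step by design.
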