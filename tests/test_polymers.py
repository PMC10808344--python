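"""Polymer chemistry: sequence generation, motif statistics, mutation,
replication bookkeeping and virtual-box conservation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hexchem import PolymerInstance, catalytic_ratio, catalytic_ratios, mutate, random_polymer1, run_length_profile
from hexchem.polymers import (
    PolymerParams,
    PolymerTriggers,
    _mutate_batch,
    box_from_monomers,
    decay_polymers1,
    decompose_box,
    decompose_boxes,
    form_boxes,
    replicate_polymers1,
)
from hexchem.species import BOUNDARY_MONOMER, MONOMER_A, MONOMER_B

from conftest import make_state

A, B = MONOMER_A, MONOMER_B


def seq(s: str) -> np.ndarray:
    return np.array([A if ch == "6" else B for ch in s], dtype=np.uint8)


# ---------------------------------------------------------------- generation


def test_initial_polymer_composition(rng):
    s = random_polymer1(0.68, rng)
    assert len(s) == 100
    assert (s == A).sum() == 68 and (s == B).sum() == 32


def test_w_one_all_motif_monomer(rng):
    assert (random_polymer1(1.0, rng) == A).all()


# ------------------------------------------------------------ motif statistic


def test_catalytic_ratio_examples():
    assert catalytic_ratio(seq("7" * 100)) == 0.0  # guard: no molecule 6
    assert catalytic_ratio(seq("6" * 100)) == pytest.approx(96 / 100)
    # no 5-run: zero windows
    assert catalytic_ratio(seq("66667" * 20)) == 0.0


def test_catalytic_ratio_reversal_invariant(rng):
    for _ in range(20):
        s = random_polymer1(0.68, rng)
        assert catalytic_ratio(s) == pytest.approx(catalytic_ratio(s[::-1]))


def test_catalytic_ratio_zero_iff_no_five_run(rng):
    for _ in range(50):
        s = random_polymer1(0.68, rng)
        has_run = "6" * 5 in "".join("6" if x == A else "7" for x in s)
        assert (catalytic_ratio(s) > 0) == has_run


def test_batch_matches_scalar(rng):
    seqs = np.stack([random_polymer1(0.68, rng) for _ in range(50)])
    batch = catalytic_ratios(seqs)
    assert np.allclose(batch, [catalytic_ratio(s) for s in seqs])


def test_neutral_shuffle_mean(rng):
    # 68:32 uniformly shuffled sequences: ensemble mean of the statistic
    # sits at the ~0.19 neutral baseline
    seqs = np.stack([random_polymer1(0.68, rng) for _ in range(5000)])
    assert catalytic_ratios(seqs).mean() == pytest.approx(0.19, abs=0.01)


def test_rejects_foreign_monomers():
    with pytest.raises(ValueError):
        catalytic_ratio(np.array([A, B, 12], dtype=np.uint8))


# ------------------------------------------------------------------ run lengths


def test_run_length_profile_by_inspection():
    assert run_length_profile(seq("6677666")) == {2: 1, 3: 1}
    assert run_length_profile(seq("7777")) == {}


def test_run_length_mass_identity(rng):
    for _ in range(30):
        s = random_polymer1(float(rng.random()), rng)
        prof = run_length_profile(s)
        assert sum(l * c for l, c in prof.items()) == (s == A).sum()


def _brute_profile(bits):
    """Independent enumerator using itertools.groupby."""
    out = {}
    for key, grp in itertools.groupby(bits):
        if key == 1:
            n = len(list(grp))
            out[n] = out.get(n, 0) + 1
    return out


def test_run_length_profile_exhaustive_length10():
    for bits in itertools.product((0, 1), repeat=10):
        s = np.where(np.array(bits) == 1, A, B).astype(np.uint8)
        assert run_length_profile(s) == _brute_profile(bits)


# --------------------------------------------------------------------- mutation


def test_mutate_zero_rate_identity(rng):
    s = random_polymer1(0.68, rng)
    assert (mutate(s, 0.0, rng) == s).all()


def test_mutate_degenerate_all_A(rng):
    s = np.full(100, A, dtype=np.uint8)
    assert (mutate(s, 1.0, rng) == s).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 100), st.integers(0, 2**31 - 1), st.floats(0, 1))
def test_mutate_preserves_composition(n6, seed, m):
    rng = np.random.default_rng(seed)
    s = np.array([A] * n6 + [B] * (100 - n6), dtype=np.uint8)
    rng.shuffle(s)
    out = mutate(s, m, rng)
    assert (out == A).sum() == n6
    assert len(out) == 100


def test_mutate_changes_arrangement_not_composition(rng):
    s = random_polymer1(0.68, rng)
    out = mutate(s, 1.0, rng)
    assert (out == A).sum() == 68
    assert (out != s).sum() == 2  # exactly one pair swapped


def test_mutation_chain_converges_to_shuffle_law():
    # Stationary law of repeated swapping is uniform over arrangements of
    # fixed composition: start far away (blocked arrangement, ratio ~0.94)
    # and relax to the neutral shuffle mean
    rng = np.random.default_rng(21)
    n_chains, n_steps = 400, 600
    start = np.array([A] * 68 + [B] * 32, dtype=np.uint8)
    seqs = np.tile(start, (n_chains, 1))
    for _ in range(n_steps):
        _mutate_batch(seqs, 1.0, rng)
    ratios = catalytic_ratios(seqs)
    assert ratios.mean() == pytest.approx(0.196, abs=0.015)
    # typical mutated-sequence ratios fluctuate within roughly 0.1-0.35
    assert np.quantile(ratios, 0.05) > 0.05
    assert np.quantile(ratios, 0.95) < 0.4


# ------------------------------------------------------------------ replication


def _template_state(n11=1, free6=68, free7=32, rng=None):
    rng = rng or np.random.default_rng(3)
    template = random_polymer1(0.68, rng)
    return (
        make_state(
            5,
            5,
            {12: {11: n11, 6: free6, 7: free7}},
            polymers=[(12, template)],
        ),
        template,
    )


def test_replication_bookkeeping(rng):
    state, template = _template_state()
    created = replicate_polymers1(state, PolymerParams(mutation_rate=0.0), rng)
    assert created == 1
    assert len(state.polymers) == 2
    flat6 = state.counts[state.species_index(6)].ravel()
    flat7 = state.counts[state.species_index(7)].ravel()
    assert flat6[12] == 0 and flat7[12] == 0  # monomers consumed exactly
    # with m=0 the copy is faithful
    assert (state.polymers.seqs[1] == template).all()
    # molecule 11 required but not consumed
    assert state.counts[state.species_index(11)].ravel()[12] == 1


def test_no_replication_without_trigger(rng):
    state, _ = _template_state(n11=0)
    assert replicate_polymers1(state, PolymerParams(), rng) == 0
    assert len(state.polymers) == 1


def test_no_replication_with_insufficient_monomers(rng):
    state, _ = _template_state(free6=67)
    assert replicate_polymers1(state, PolymerParams(), rng) == 0


def test_replication_copy_mutates_with_m1(rng):
    state, template = _template_state()
    replicate_polymers1(state, PolymerParams(mutation_rate=1.0), rng)
    copy = state.polymers.seqs[1]
    assert (copy == A).sum() == (template == A).sum()  # composition kept
    assert (copy != template).sum() == 2


# ----------------------------------------------------------------- virtual boxes


def test_form_then_decompose_round_trip(rng):
    state = make_state(5, 5, {12: {12: 100_000, 13: 50}})
    mass0 = state.boundary_monomer_mass()
    trig = PolymerTriggers(formation_p=1.0, box_decay_p=1.0)
    formed = form_boxes(state, trig, rng)
    assert formed == 50  # limited by the trigger count
    assert state.boundary_monomer_mass() == mass0
    decomposed = decompose_boxes(state, trig, rng)
    assert decomposed == 50
    assert state.total_count(12) == 100_000  # free counts restored exactly
    assert state.boxes2.sum() == 0


def test_formation_insufficient_monomers_noop(rng):
    state = make_state(5, 5, {12: {12: 99, 13: 10}})
    assert form_boxes(state, PolymerTriggers(formation_p=1.0), rng) == 0


def test_boundary_mass_invariant_under_random_triggers():
    rng = np.random.default_rng(17)
    state = make_state(6, 6)
    state.counts[state.species_index(12)] = rng.integers(0, 5000, (6, 6))
    state.counts[state.species_index(13)] = rng.integers(0, 10, (6, 6))
    mass0 = state.boundary_monomer_mass()
    for _ in range(500):
        trig = PolymerTriggers(
            formation_p=float(rng.random()), box_decay_p=float(rng.random())
        )
        if rng.random() < 0.5:
            form_boxes(state, trig, rng)
        else:
            decompose_boxes(state, trig, rng)
        assert state.boundary_monomer_mass() == mass0


def test_polymer_decay_returns_monomers(rng):
    state = make_state(5, 5, polymers=[(7, random_polymer1(0.68, rng))])
    decayed = decay_polymers1(state, PolymerTriggers(polymer1_decay_p=1.0), rng)
    assert decayed == 1 and len(state.polymers) == 0
    assert state.counts[state.species_index(6)].ravel()[7] == 68
    assert state.counts[state.species_index(7)].ravel()[7] == 32


def test_api_level_box_round_trip():
    counts = {BOUNDARY_MONOMER: 150}
    box = box_from_monomers(counts)
    assert counts[BOUNDARY_MONOMER] == 50 and box.full and box.ptype == 2
    decompose_box(box, counts)
    assert counts[BOUNDARY_MONOMER] == 150
    with pytest.raises(ValueError):
        box_from_monomers({BOUNDARY_MONOMER: 99})


def test_polymer_instance_validation():
    with pytest.raises(ValueError):
        PolymerInstance(1, (A,) * 101)
    with pytest.raises(ValueError):
        PolymerInstance(1, (12,) * 10)
    with pytest.raises(ValueError):
        PolymerInstance(3, (A,) * 10)
    assert not PolymerInstance(1, (A,) * 10).full


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        PolymerParams(w=1.2)
    with pytest.raises(ValueError):
        PolymerParams(mutation_rate=-0.1)
    with pytest.raises(ValueError):
        PolymerTriggers(formation_p=2.0)
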