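import numpy as np
import pytest

from hexchem import HexGrid, LatticeState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(width=5, height=5, cell_counts=None, polymers=None):
    """Small lattice state for unit tests.

    ``cell_counts``: {flat_cell: {species_id: count}};
    ``polymers``: list of (flat_cell, sequence array).
    """
    state = LatticeState(HexGrid(width, height))
    for cell, spec in (cell_counts or {}).items():
        r, c = state.grid.rowcol(cell)
        for sid, n in spec.items():
            state.counts[state.species_index(sid), r, c] = n
    if polymers:
        cells = np.array([c for c, _ in polymers], dtype=np.int64)
        seqs = np.stack([np.asarray(s, dtype=np.uint8) for _, s in polymers])
        state.polymers.add(cells, seqs)
    return state


@pytest.fixture
def state_factory():
    return make_state
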