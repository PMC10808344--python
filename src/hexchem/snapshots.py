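"""Snapshot writers: per-step species-count arrays and polymer sequences.

Counts go to a compressed ``.npz`` container (one array per species plus the
boundary-box counts); informant sequences go to a JSON-lines sidecar, one
object per instance with the sequence spelled in the {6: "A", 7: "B",
12: "M"} alphabet.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .polymers import seq_to_str, str_to_seq
from .state import LatticeState


def write_snapshot(state: LatticeState, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.npz`` and ``<prefix>.polymers.jsonl``; returns both
    paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"mol{sid}": state.counts[state.species_index(sid)] for sid in state.species_ids}
    arrays["boxes2"] = state.boxes2
    arrays["step"] = np.array(state.step)
    npz = prefix.with_suffix(".npz")
    np.savez_compressed(npz, **arrays)
    jsonl = prefix.with_suffix(".polymers.jsonl")
    with open(jsonl, "w") as fh:
        for cell, seq in zip(state.polymers.cells, state.polymers.seqs):
            fh.write(json.dumps({"cell": int(cell), "ptype": 1, "seq": seq_to_str(seq)}) + "\n")
    return npz, jsonl


def read_polymer_lines(path: str | Path) -> list[tuple[int, np.ndarray]]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append((int(rec["cell"]), str_to_seq(rec["seq"])))
    return out
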