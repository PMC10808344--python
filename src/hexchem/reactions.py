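"""Probabilistic multiset-rewriting engine.

Each reaction rule rewrites a reactant multiset into a product multiset with
probability ``p`` per candidate event, inside every cell independently.  The
number of candidate events in a cell is limited by the scarcest reactant
(``min_s floor(count_s / multiplicity_s)``); the realised event count is the
stochastic rounding of ``candidates * p``, so the expected update matches the
mean-field form ``A(t+1) = A(t) * (1 - p)`` while staying integral.
Catalyst-conditioned rules (the ``a + b => a + c`` pattern) fire only while
every catalyst species is present; writing the catalyst on both sides of the
rule instead makes the event count proportional to its abundance.

Rules apply sequentially in listed order on live counts, which both fixes
the draw order (reproducibility) and makes over-spending impossible.  When a
rule carries an energy cost, events are truncated to the molecule-25 budget
and the spent carriers become waste molecule 19.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, MutableMapping

import numpy as np
import yaml

from ._util import stochastic_round
from .energy import consume_energy
from .polymers import PolymerTriggers
from .species import ENERGY, MOLECULE_IDS


class NetworkConfigError(ValueError):
    """Raised for malformed reaction-network documents."""


def _as_multiset(obj, what: str) -> dict[int, int]:
    """Accept ``{species: multiplicity}`` or a list of species ids."""
    if obj is None:
        return {}
    if isinstance(obj, Mapping):
        ms = {int(k): int(v) for k, v in obj.items()}
    else:
        ms = {}
        for s in obj:
            ms[int(s)] = ms.get(int(s), 0) + 1
    for s, k in ms.items():
        if s not in MOLECULE_IDS:
            raise NetworkConfigError(f"{what}: unknown species {s}")
        if k <= 0:
            raise NetworkConfigError(f"{what}: non-positive multiplicity for {s}")
    return ms


@dataclass(frozen=True)
class ReactionRule:
    """One multiset rewrite: ``reactants -> products`` with probability
    ``probability`` per candidate event, gated on ``catalysts`` being
    present (catalysts are not consumed), consuming ``energy_cost`` molecule
    25 per event."""

    reactants: Mapping[int, int]
    products: Mapping[int, int]
    catalysts: Mapping[int, int] = field(default_factory=dict)
    probability: float = 1.0
    energy_cost: int = 0

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(_as_multiset(self.reactants, "reactants")))
        object.__setattr__(self, "products", dict(_as_multiset(self.products, "products")))
        object.__setattr__(self, "catalysts", dict(_as_multiset(self.catalysts, "catalysts")))
        if not self.reactants or not self.products:
            raise NetworkConfigError("reactant and product multisets must be non-empty")
        if not 0.0 <= self.probability <= 1.0:
            raise NetworkConfigError(f"probability {self.probability} outside [0, 1]")
        if self.energy_cost < 0:
            raise NetworkConfigError(f"negative energy cost {self.energy_cost}")

    @property
    def conserves_count(self) -> bool:
        return sum(self.reactants.values()) == sum(self.products.values())


@dataclass(frozen=True)
class ReactionNetwork:
    """Ordered rule list.  With ``conservation_flag`` set, every rule must
    conserve total molecule count (reactant size == product size), making
    the lattice-wide total over species 1-15 invariant."""

    rules: tuple[ReactionRule, ...] = ()
    conservation_flag: bool = True

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        if self.conservation_flag:
            for i, r in enumerate(self.rules):
                if not r.conserves_count:
                    raise NetworkConfigError(
                        f"rule {i}: {dict(r.reactants)} -> {dict(r.products)} "
                        "does not conserve molecule count"
                    )


def apply_rule(
    counts: MutableMapping[int, np.ndarray],
    rule: ReactionRule,
    rng: np.random.Generator,
    max_events=None,
) -> np.ndarray:
    """Fire one rule against a count mapping (scalars or arrays), in place.

    Returns the realised event count (same shape as the counts).  Counts can
    never go negative: events are bounded by the scarcest reactant before
    the probability draw.
    """
    limit = None
    for s, k in rule.reactants.items():
        q = np.asarray(counts[s]) // k
        limit = q if limit is None else np.minimum(limit, q)
    for s, k in rule.catalysts.items():
        gate = np.asarray(counts[s]) >= k
        limit = np.where(gate, limit, 0)
    events = np.minimum(stochastic_round(limit * rule.probability, rng), limit)
    if max_events is not None:
        events = np.minimum(events, max_events)
    for s, k in rule.reactants.items():
        counts[s] -= k * events
    for s, k in rule.products.items():
        counts[s] += k * events
    return events


def apply_network(
    counts: MutableMapping[int, np.ndarray],
    network: ReactionNetwork,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fire every rule in listed order.  Energy-costing rules draw on the
    live molecule-25 stock, first come first served; their events are
    truncated so consumption never exceeds availability, and each granted
    event converts ``energy_cost`` molecules 25 to waste 19.  Returns total
    events summed over rules."""
    total = None
    for rule in network.rules:
        if rule.energy_cost > 0:
            budget = np.asarray(counts[ENERGY]) // rule.energy_cost
            events = apply_rule(counts, rule, rng, max_events=budget)
            consume_energy(counts, events, rule.energy_cost)
        else:
            events = apply_rule(counts, rule, rng)
        total = events if total is None else total + events
    if total is None:
        total = np.zeros_like(np.asarray(counts[ENERGY]))
    return total


# ---------------------------------------------------------------------------
# Configuration documents
# ---------------------------------------------------------------------------


def load_network(doc: Mapping) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork` from a config document
    (the parsed YAML/JSON mapping with ``rules`` and ``conservation``
    keys)."""
    if not isinstance(doc, Mapping):
        raise NetworkConfigError("network document must be a mapping")
    unknown = set(doc) - {"rules", "conservation", "polymer_triggers"}
    if unknown:
        raise NetworkConfigError(f"unknown network config keys: {sorted(unknown)}")
    rules = []
    for i, rd in enumerate(doc.get("rules", ())):
        extra = set(rd) - {"reactants", "products", "catalysts", "p", "energy_cost"}
        if extra:
            raise NetworkConfigError(f"rule {i}: unknown keys {sorted(extra)}")
        try:
            rules.append(
                ReactionRule(
                    reactants=rd.get("reactants"),
                    products=rd.get("products"),
                    catalysts=rd.get("catalysts"),
                    probability=float(rd.get("p", 1.0)),
                    energy_cost=int(rd.get("energy_cost", 0)),
                )
            )
        except NetworkConfigError as e:
            raise NetworkConfigError(f"rule {i}: {e}") from None
    return ReactionNetwork(tuple(rules), bool(doc.get("conservation", True)))


def load_triggers(doc: Mapping) -> PolymerTriggers:
    td = doc.get("polymer_triggers") or {}
    known = {"formation_catalyst", "formation_p", "box_decay_p", "polymer1_decay_p"}
    unknown = set(td) - known
    if unknown:
        raise NetworkConfigError(f"unknown polymer_triggers keys: {sorted(unknown)}")
    return PolymerTriggers(**td)


def load_network_file(path: str | Path) -> tuple[ReactionNetwork, PolymerTriggers]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return load_network(doc), load_triggers(doc)


def default_network_doc() -> dict:
    ref = importlib.resources.files("hexchem") / "networks" / "default.yaml"
    return yaml.safe_load(ref.read_text())


def default_network() -> tuple[ReactionNetwork, PolymerTriggers]:
    """The bundled 15-species cyclic network and its polymer triggers."""
    doc = default_network_doc()
    return load_network(doc), load_triggers(doc)
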