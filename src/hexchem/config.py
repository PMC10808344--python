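"""Run configuration: schema-validated YAML/JSON documents.

A run config mirrors the standard parameter table plus the experiment block
(energy supply or schedule, mutation rate, horizon, seeds).  Unknown keys
are rejected and validation errors carry the offending field path.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .energy import EnergySchedule
from .experiment import TrialConfig
from .polymers import PolymerParams, PolymerTriggers
from .reactions import load_network_file
from .species import Species, SpeciesTable


class ConfigError(ValueError):
    """Invalid run configuration (schema violation, with field path)."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSection(_Model):
    width: int = Field(100, ge=3)
    height: int = Field(100, ge=3)


class SpeciesRow(_Model):
    species_id: int
    residual_rate: float = Field(ge=0.0, le=1.0)
    initial_global: int = Field(0, ge=0)
    initial_central: int | None = Field(None, ge=0)


class PolymerSection(_Model):
    w: float = Field(0.68, ge=0.0, le=1.0)
    mutation_rate: float = Field(0.1, ge=0.0, le=1.0)
    resident_mutation_p: float = Field(0.0, ge=0.0, le=1.0)
    polymer1_residual_rate: float = Field(0.75, ge=0.0, le=1.0)
    polymer2_residual_rate: float = Field(0.75, ge=0.0, le=1.0)
    initial_central_polymers: int = Field(10, ge=0)


class TriggerSection(_Model):
    formation_catalyst: int | None = 13
    formation_p: float = Field(0.2, ge=0.0, le=1.0)
    box_decay_p: float = Field(0.01, ge=0.0, le=1.0)
    polymer1_decay_p: float = Field(0.01, ge=0.0, le=1.0)


class ScheduleEntry(_Model):
    from_step: int = Field(ge=0)
    E: int = Field(ge=0)


class ExperimentSection(_Model):
    E: int = Field(800, ge=0)
    schedule: list[ScheduleEntry] | None = None
    mutation_rate: float | None = None  # overrides polymer.mutation_rate
    max_steps: int = Field(8000, ge=0)
    seed: int = 0
    n_trials: int = Field(10, ge=1)
    central_radius: int = Field(3, ge=0)


class RenderSection(_Model):
    scale: int = Field(6, ge=2)


class RunConfig(_Model):
    """Top-level run configuration with standard-case defaults."""

    grid: GridSection = Field(default_factory=GridSection)
    species: list[SpeciesRow] | None = None  # None -> standard table
    network: str | None = None  # path to a network YAML; None -> bundled default
    polymer: PolymerSection = Field(default_factory=PolymerSection)
    triggers: TriggerSection | None = None  # None -> network file's triggers
    experiment: ExperimentSection = Field(default_factory=ExperimentSection)
    output_dir: str = "out"
    render: RenderSection = Field(default_factory=RenderSection)

    def species_table(self) -> SpeciesTable:
        if self.species is None:
            return SpeciesTable(
                polymer1_residual_rate=self.polymer.polymer1_residual_rate,
                polymer2_residual_rate=self.polymer.polymer2_residual_rate,
                polymer1_initial_central=self.polymer.initial_central_polymers,
            )
        rows = tuple(
            Species(r.species_id, r.residual_rate, r.initial_global, r.initial_central)
            for r in self.species
        )
        try:
            return SpeciesTable(
                rows,
                self.polymer.polymer1_residual_rate,
                self.polymer.polymer2_residual_rate,
                self.polymer.initial_central_polymers,
            )
        except ValueError as e:
            raise ConfigError(f"species: {e}") from None

    def energy_schedule(self) -> EnergySchedule:
        if self.experiment.schedule is not None:
            return EnergySchedule(
                tuple((e.from_step, e.E) for e in self.experiment.schedule)
            )
        return EnergySchedule.constant(self.experiment.E)

    def trial_config(self, seed: int | None = None) -> TrialConfig:
        """Materialise a :class:`TrialConfig` (loads the network file if one
        is configured)."""
        network = triggers = None
        if self.network is not None:
            network, triggers = load_network_file(self.network)
        if self.triggers is not None:
            triggers = PolymerTriggers(**self.triggers.model_dump())
        m = (
            self.experiment.mutation_rate
            if self.experiment.mutation_rate is not None
            else self.polymer.mutation_rate
        )
        return TrialConfig(
            width=self.grid.width,
            height=self.grid.height,
            species=self.species_table(),
            network=network,
            triggers=triggers,
            params=PolymerParams(
                w=self.polymer.w,
                mutation_rate=m,
                resident_mutation_p=self.polymer.resident_mutation_p,
            ),
            energy=self.energy_schedule(),
            max_steps=self.experiment.max_steps,
            seed=self.experiment.seed if seed is None else seed,
            central_radius=self.experiment.central_radius,
        ).resolved()


def _format_validation_error(e: ValidationError) -> str:
    lines = []
    for err in e.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run config; defaults fill every
    omitted field."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_config(doc or {})


def parse_config(doc: dict) -> RunConfig:
    try:
        cfg = RunConfig.model_validate(doc)
    except ValidationError as e:
        raise ConfigError(_format_validation_error(e)) from None
    cfg.species_table()  # cross-field checks (complete id set etc.)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    doc = cfg.model_dump(exclude_none=True)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)
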