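"""Simulation configuration: defaults, profiles, and YAML round-tripping.

The ``paper`` profile carries the full-scale study conditions (1000x1000
grid, 100 kb genomes, up to 20,000 organisms, 2000 steps).  The ``desk``
profile is a scaled-down preset (200x200 grid, 20 kb genomes, 2000-cell
cap, 500 steps) used for quick experiments and the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .genome import DEFAULT_KIND_WORDS


@dataclass
class ScenarioConfig:
    """Food-removal scenario parameters (see ``world.RemovalSchedule``)."""

    mode: str = "none"  # none | dynamic | fixed
    fraction: float = 0.0
    period: int = 60
    pop_trigger: int = 1000
    fixed_step: int = 300


@dataclass
class SimulationConfig:
    # world
    width: int = 1000
    height: int = 1000
    n_food_init: int = 100
    food_init_low: float = 10_000.0
    food_init_high: float = 20_000.0
    # population
    n_do_init: int = 200
    initial_energy: float = 10_000.0
    population_cap: int = 20_000
    founder_min_regulatory: int = 12
    # genome & mutation
    genome_length: int = 100_000
    wgd_rate: float = 0.40
    substitution_rate: float = 1e-4
    # behavior & energetics
    move_cost: float = 70.0
    upkeep_cost: float = 70.0  # per-step metabolic drain, movement aside
    replication_threshold: float = 20_000.0
    sensing_radius: int = 5
    offspring_energy: str = "split"  # split | copy
    # GRN knobs
    expression_threshold: float = 1.0
    concentration_cap: float = 100.0
    decay_low: float = 0.05
    decay_high: float = 0.25
    bootstrap_tfs: int = 12
    bootstrap_value: float = 10.0
    stability_window: int = 10
    # scenario & stopping
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    max_steps: int = 2000
    stop_at_population_cap: bool = True
    stop_on_class_extinction: bool = True
    stop_at_equalization: bool = False
    # selection switch: free energy, no movement cost, no food dependence
    # (used for neutral-null experiments)
    selection_disabled: bool = False
    # logging
    log_records: bool = False
    log_grn_traces: bool = False
    # randomness
    master_seed: int = 0
    # grammar
    kind_words: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_KIND_WORDS)
    )

    def __post_init__(self) -> None:
        for name in ("wgd_rate", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "width",
            "height",
            "n_do_init",
            "genome_length",
            "population_cap",
            "max_steps",
        ):
            if getattr(self, name) < 0 or (
                name not in ("max_steps",) and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.offspring_energy not in ("split", "copy"):
            raise ValueError("offspring_energy must be 'split' or 'copy'")
        if self.scenario.mode not in ("none", "dynamic", "fixed"):
            raise ValueError(f"unknown scenario mode {self.scenario.mode!r}")

    # -- profiles ----------------------------------------------------------
    @classmethod
    def paper(cls, **overrides) -> "SimulationConfig":
        """Full-scale study conditions."""
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "SimulationConfig":
        """Scaled-down preset: 200x200 grid, 20 kb genomes, 2000-cell cap,
        500 steps.  Food supply and the founder regulatory-gene requirement
        are scaled to match (see docs/methods.md)."""
        params = dict(
            width=200,
            height=200,
            population_cap=2000,
            max_steps=500,
            genome_length=20_000,
            n_food_init=1200,
            founder_min_regulatory=2,
        )
        params.update(overrides)
        return cls(**params)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "scenario" in data and isinstance(data["scenario"], dict):
            sc = data["scenario"]
            sc_known = {f.name for f in dataclasses.fields(ScenarioConfig)}
            sc_unknown = set(sc) - sc_known
            if sc_unknown:
                raise ValueError(
                    f"unknown scenario keys: {sorted(sc_unknown)}"
                )
            data["scenario"] = ScenarioConfig(**sc)
        return cls(**data)

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ValueError("configuration document must be a mapping")
        return cls.from_dict(data)


def profile(name: str, **overrides) -> SimulationConfig:
    if name == "paper":
        return SimulationConfig.paper(**overrides)
    if name == "desk":
        return SimulationConfig.desk(**overrides)
    raise ValueError(f"unknown profile {name!r} (expected 'paper' or 'desk')")
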