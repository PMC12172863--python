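"""Validated run configuration for the command-line pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "GeometryConfig", "AcquisitionConfig", "SimulationConfig",
           "InverseConfig", "LocalizeConfig", "EvaluateConfig", "load_config"]


@dataclass
class GeometryConfig:
    subdivisions: int = 4
    radius: float = 35.0
    fold_amplitude: float = 5.0
    hemisphere_gap: float = 8.0
    band_width: float = 0.19
    head_radius: float = 85.0

    def validate(self) -> None:
        if not 0 <= self.subdivisions <= 7:
            raise ValueError("geometry.subdivisions must be in [0, 7]")
        if self.fold_amplitude >= self.radius / 4:
            raise ValueError("geometry.fold_amplitude must be < radius/4")
        if self.head_radius <= self.radius:
            raise ValueError("geometry.head_radius must exceed the hemisphere radius")


@dataclass
class AcquisitionConfig:
    n_mag: int = 102
    n_grad_pairs: int = 102
    helmet_radius: float = 110.0

    def validate(self) -> None:
        if self.n_mag < 1 or self.n_grad_pairs < 0:
            raise ValueError("acquisition channel counts invalid")


@dataclass
class SimulationConfig:
    n_patients: int = 4
    sides: str = "UL"  # "UL", "UR" or "both" (alternating)
    snr: float = 5.0
    n_epochs: int | None = None
    patch_size: int = 50
    moment_total: float = 50.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("simulation.n_patients must be >= 1")
        if self.snr <= 0:
            raise ValueError("simulation.snr must be positive")
        if self.patch_size < 1:
            raise ValueError("simulation.patch_size must be >= 1")
        if self.sides not in ("UL", "UR", "both"):
            raise ValueError("simulation.sides must be 'UL', 'UR' or 'both'")


@dataclass
class InverseConfig:
    lam2: float = 1.0 / 9.0

    def validate(self) -> None:
        if self.lam2 < 0:
            raise ValueError("inverse.lam2 must be non-negative")


@dataclass
class LocalizeConfig:
    filter_radius: float = 5.0
    window: tuple[float, float] = (15.0, 60.0)
    threshold: float = 0.80
    semantics: str = "fraction_of_max"
    label_respecting: bool = True

    def validate(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("localize.threshold must be in (0, 1]")
        if self.semantics not in ("fraction_of_max", "quantile"):
            raise ValueError("localize.semantics unknown")
        if self.filter_radius < 0:
            raise ValueError("localize.filter_radius must be non-negative")


@dataclass
class EvaluateConfig:
    n_permutations: int = 10_000
    p0: float = 0.05
    binomial_mode: str = "tail"

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("evaluate.n_permutations must be >= 1")
        if not 0 < self.p0 < 1:
            raise ValueError("evaluate.p0 must be in (0, 1)")
        if self.binomial_mode not in ("tail", "all_success_mass"):
            raise ValueError("evaluate.binomial_mode unknown")


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inverse: InverseConfig = field(default_factory=InverseConfig)
    localize: LocalizeConfig = field(default_factory=LocalizeConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    seed: int = 0

    def validate(self) -> None:
        for section in (self.geometry, self.acquisition, self.simulation,
                        self.inverse, self.localize, self.evaluate):
            section.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["localize"]["window"] = list(d["localize"]["window"])
        return d


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in config section '{name}': {sorted(unknown)}")
    if "window" in data and data["window"] is not None:
        data = {**data, "window": tuple(data["window"])}
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data.update(overrides)
    sections = {
        "geometry": GeometryConfig,
        "acquisition": AcquisitionConfig,
        "simulation": SimulationConfig,
        "inverse": InverseConfig,
        "localize": LocalizeConfig,
        "evaluate": EvaluateConfig,
    }
    unknown = set(data) - set(sections) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = _build_section(cls, dict(data.get(name) or {}), name)
    cfg = RunConfig(seed=int(data.get("seed", 0)), **kwargs)
    cfg.validate()
    return cfg
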