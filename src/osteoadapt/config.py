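"""Run configuration: YAML/JSON loading, validation, defaulting, echoing.

Every block is optional; omitted keys take the study defaults (constrained
lateral edges, uniform initial density 0.8 g/cm^3, reference stimulus
0.008 J/g, equilibrium-zone half-width 15%).  Unknown keys are rejected
with the offending key named.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fem import LoadCase
from .geometry import GeometryParams
from .materials import MaterialTable
from .remodeling import RemodelingParams
from .simulate import DEFAULT_SNAPSHOT_ITERATIONS

__all__ = ["RunConfig", "SimulationOptions", "OutputOptions", "load_config"]


@dataclass(frozen=True)
class SimulationOptions:
    """Loop options outside the remodeling rule itself."""

    initial_density: float = 0.8
    initial_perturbation: float = 0.0
    snapshot_iterations: tuple = DEFAULT_SNAPSHOT_ITERATIONS

    def __post_init__(self) -> None:
        if self.initial_density <= 0:
            raise ValueError("initial_density must be > 0")
        if not 0.0 <= self.initial_perturbation < 1.0:
            raise ValueError("initial_perturbation must be in [0, 1)")
        object.__setattr__(self, "snapshot_iterations",
                           tuple(int(i) for i in self.snapshot_iterations))


@dataclass(frozen=True)
class OutputOptions:
    directory: str = "results"
    formats: tuple = ("csv", "vtk", "png")

    def __post_init__(self) -> None:
        formats = tuple(self.formats)
        for f in formats:
            if f not in ("csv", "vtk", "png"):
                raise ValueError(f"output.formats: unknown format '{f}'")
        object.__setattr__(self, "formats", formats)


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: MaterialTable = field(default_factory=MaterialTable)
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    load: LoadCase = field(default_factory=LoadCase)
    simulation: SimulationOptions = field(default_factory=SimulationOptions)
    output: OutputOptions = field(default_factory=OutputOptions)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geometry),
            "materials": self.materials.to_dict(),
            "remodeling": dataclasses.asdict(self.remodeling),
            "load": dataclasses.asdict(self.load),
            "simulation": {
                "initial_density": self.simulation.initial_density,
                "initial_perturbation": self.simulation.initial_perturbation,
                "snapshot_iterations": list(self.simulation.snapshot_iterations),
            },
            "output": {
                "directory": self.output.directory,
                "formats": list(self.output.formats),
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict | None) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, sub in (
            ("geometry", GeometryParams),
            ("remodeling", RemodelingParams),
            ("load", LoadCase),
            ("simulation", SimulationOptions),
            ("output", OutputOptions),
        ):
            block = data.pop(name, None)
            kwargs[name] = _dataclass_from_dict(sub, block, name)
        mat_block = data.pop("materials", None)
        try:
            kwargs["materials"] = MaterialTable.from_dict(mat_block)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        seed = data.pop("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError(f"seed must be an integer, got {seed!r}")
        if data:
            raise ConfigError(f"unknown top-level config keys: {sorted(data)}")
        return cls(seed=seed, **kwargs)


class ConfigError(ValueError):
    """Configuration schema or range violation."""


def _dataclass_from_dict(cls, block: dict | None, context: str):
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(block).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML or JSON config; None or an empty file yields
    the all-defaults configuration."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else None
    else:
        data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return RunConfig.from_dict(data)
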