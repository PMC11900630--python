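"""Run configuration: YAML-backed, validated, fully echoable.

A :class:`RunConfig` captures everything a study run depends on — network
source (file or generator spec), physiological constants, rheology
coefficients, solver options and the conditions table — so that a run is
reproducible from its echoed config alone.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .rheology import RheologyCoefficients
from .solver import SolverOptions
from .synthetic import GeneratorSpec
from .units import PhysioConstants

__all__ = ["RunConfig", "load_config", "default_config"]

_SECTIONS = {
    "physio": PhysioConstants,
    "rheology": RheologyCoefficients,
    "solver": SolverOptions,
    "generator": GeneratorSpec,
}


@dataclass
class RunConfig:
    physio: PhysioConstants = field(default_factory=PhysioConstants)
    rheology: RheologyCoefficients = field(default_factory=RheologyCoefficients)
    solver: SolverOptions = field(default_factory=SolverOptions)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    network_file: str | None = None
    conditions_file: str | None = None
    output_dir: str = "glomflow_out"

    def to_dict(self) -> dict:
        d = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        d["rheology"]["oncotic"] = list(d["rheology"]["oncotic"])
        d.update(
            network_file=self.network_file,
            conditions_file=self.conditions_file,
            output_dir=self.output_dir,
        )
        return d

    def echo_yaml(self) -> str:
        """Serialise the active configuration (for run logs)."""
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(self.echo_yaml())
        return Path(path)


def _build_section(cls, payload: dict, section: str):
    fields = cls.__dataclass_fields__
    unknown = set(payload) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    coerced = {}
    for key, value in payload.items():
        ftype = fields[key].type
        if ftype == "float" and isinstance(value, (int, str)):
            value = float(value)  # YAML 1.1 treats e.g. 1.0e9 as a string
        elif ftype == "int" and isinstance(value, str):
            value = int(value)
        coerced[key] = value
    if "oncotic" in coerced:
        coerced["oncotic"] = tuple(float(v) for v in coerced["oncotic"])
    return cls(**coerced)


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML run config; ``None`` loads the packaged defaults.

    ``seed`` overrides the generator seed without editing the file.
    """
    if path is None:
        ref = importlib.resources.files("glomflow.data").joinpath("default.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = set(_SECTIONS) | {"network_file", "conditions_file", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    sections = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    cfg = RunConfig(
        **sections,
        network_file=raw.get("network_file"),
        conditions_file=raw.get("conditions_file"),
        output_dir=raw.get("output_dir", "glomflow_out"),
    )
    if seed is not None:
        cfg.generator = GeneratorSpec(**{**asdict(cfg.generator), "seed": seed})
    return cfg


def default_config(seed: int | None = None) -> RunConfig:
    return load_config(None, seed=seed)
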