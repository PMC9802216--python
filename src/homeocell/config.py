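"""Run configuration: YAML parsing, validation, defaults, serialization.

A run configuration collects the physical and numerical parameters of the
simulator in sections mirroring the library modules::

    load:      eps_amp, f, r, eps_mean            (substrate strain protocol)
    cell:      R0, R_N, moduli, exponents, ...    (passive elasticity)
    sf:        sigma_max, k_v, eps_rate_0, ...    (stress-fiber model)
    sampling:  n_samples, a_min, a_max, n_time    (ensemble solve)
    langevin:  dt_hat, t_end_hat, n_traj, ...     (kinetics)
    output:    directory, formats

Unknown keys are rejected so typos fail loudly; an empty file yields the
calibrated defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from homeocell.kinetics import LangevinSettings
from homeocell.mechanics import CellParams, CyclicLoad
from homeocell.sf import SFParams

__all__ = ["SamplingSettings", "OutputSettings", "RunConfig", "load_config", "dump_config"]


@dataclass
class SamplingSettings:
    """Phase-space sampling and quadrature settings for the ensemble."""

    n_samples: int = 20000
    a_min: float = 0.3
    a_max: float = 4.0
    n_time: int = 64
    theta_bins: int = 36
    scalar_bins: int = 40

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (0 < self.a_min < self.a_max):
            raise ValueError("require 0 < a_min < a_max")
        if self.n_time < 8:
            raise ValueError("n_time must be >= 8")


@dataclass
class OutputSettings:
    directory: str = "homeocell_out"


_SECTIONS = {
    "load": CyclicLoad,
    "cell": CellParams,
    "sf": SFParams,
    "sampling": SamplingSettings,
    "langevin": LangevinSettings,
    "output": OutputSettings,
}


@dataclass
class RunConfig:
    """Validated configuration for a simulator run."""

    load: CyclicLoad = field(default_factory=CyclicLoad)
    cell: CellParams = field(default_factory=CellParams)
    sf: SFParams = field(default_factory=SFParams)
    sampling: SamplingSettings = field(default_factory=SamplingSettings)
    langevin: LangevinSettings = field(default_factory=LangevinSettings)
    output: OutputSettings = field(default_factory=OutputSettings)
    base_seed: int = 0

    def to_dict(self) -> dict:
        d = {}
        for name in _SECTIONS:
            section = dataclasses.asdict(getattr(self, name))
            section.pop("H_s", None)  # derived cache, not configuration
            d[name] = section
        d["base_seed"] = self.base_seed
        return d

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build_section(name: str, cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) in section [{name}]: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section [{name}]: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing sections get defaults."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    if overrides:
        for key, sub in overrides.items():
            if isinstance(sub, dict):
                data.setdefault(key, {}).update(sub)
            else:
                data[key] = sub
    unknown = set(data) - set(_SECTIONS) - {"base_seed"}
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name) or {}
        if not isinstance(section, dict):
            raise ValueError(f"section [{name}] must be a mapping")
        if name == "cell":
            section.pop("H_s", None)
        kwargs[name] = _build_section(name, cls, section)
    seed = data.get("base_seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ValueError("base_seed must be a nonnegative integer")
    return RunConfig(base_seed=seed, **kwargs)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config to YAML; load_config(dump_config(c)) round-trips."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
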