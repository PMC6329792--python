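"""Run configuration: schema-checked stage parameters for the pipelines.

Configs load from YAML or JSON. Unknown keys are rejected at every level so
a typo fails loudly rather than silently running defaults, and a config
round-trips through serialization unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SafetyStageConfig:
    heating_power_bound_w: float = 0.15
    breakdown_energy_at_surface_j: float = 130e-9
    anchor_energy_j: float = 10e-9
    anchor_rate_hz: float = 800e3
    anchor_width_s: float = 40e-15
    mode: str = "constant_pulse_signal"
    r_min_hz: float = 2e5
    r_max_hz: float = 2e7
    n_points: int = 50


@dataclass(frozen=True)
class OpticsStageConfig:
    ablation_extinction_length_um: float = 270.3
    threshold_fluence_j_cm2: float = 1.04
    fwhm_3p_um: float = 0.45
    thg_extinction_lengths_um: tuple = (242.0, 107.0)
    thg_segment_breaks_um: tuple = (600.0,)
    depths_um: tuple = (150.0, 300.0, 450.0, 600.0)

    def __post_init__(self) -> None:
        for name in ("thg_extinction_lengths_um", "thg_segment_breaks_um", "depths_um"):
            object.__setattr__(self, name, tuple(getattr(self, name)))


@dataclass(frozen=True)
class TransportStageConfig:
    n_photons: int = 100_000
    depth_um: float = 1000.0
    scattering_length_um: float = 75.0
    absorption_length_um: float = 1000.0
    anisotropy_g: float = 0.93
    thickness_um: float = 1200.0
    aperture_radius_mm: float = 12.7
    aperture_distance_mm: float = 25.0
    acceptance_half_angle_deg: float = 90.0


@dataclass(frozen=True)
class TuningStageConfig:
    n_neurons: int = 40
    fraction_responsive: float = 0.5
    noise_sd: float = 0.1
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: stages to run plus their parameters."""

    stages: tuple = ()
    seed: int = 0
    output_dir: str = "threephoton_out"
    verbosity: int = 1
    safety: SafetyStageConfig = field(default_factory=SafetyStageConfig)
    optics: OpticsStageConfig = field(default_factory=OpticsStageConfig)
    transport: TransportStageConfig = field(default_factory=TransportStageConfig)
    tuning: TuningStageConfig = field(default_factory=TuningStageConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("top level: expected a mapping")
        data = dict(data)
        sub = {}
        for key, sub_cls in (
            ("safety", SafetyStageConfig),
            ("optics", OpticsStageConfig),
            ("transport", TransportStageConfig),
            ("tuning", TuningStageConfig),
        ):
            if key in data:
                sub[key] = _from_mapping(sub_cls, data.pop(key), key)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        cfg = _from_mapping(cls, {**data, **sub}, "top level")
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        for k in ("optics",):
            for kk, v in d[k].items():
                if isinstance(v, tuple):
                    d[k][kk] = list(v)
        return d
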