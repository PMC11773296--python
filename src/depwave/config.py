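"""Run configuration: YAML schema, validation, and construction helpers.

One human-editable YAML file describes a full run; every CLI flag
overrides the corresponding key. Example::

    system:
      eps_r_particle: 2.55
      sigma_particle: 0.0        # S/m (bulk)
      eps_r_medium: 78.5
      sigma_medium: 1.0e-4       # S/m
      radius: 1.24e-6            # m
      surface_conductance: 1.0e-9  # S, optional (default 0)
    waveform:
      shape: rectangular
      v0: 5.0                    # V peak
      f0: 15.0e3                 # Hz
      max_order: 199
      bandwidth_limit: null      # Hz, optional
      rolloff: brickwall         # or first_order
    analysis:
      field_gradient: 1.0e13     # V^2/m^3
      comparison: equal-peak     # or equal-rms
    efficiency:
      baseline_window: [10.0, 55.0]
      eval_window: [225.0, 245.0]
      schedule: [70.0, 250.0]
    seed: 0
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dielectrics import DielectricMaterial, ParticleSystem
from .errors import ConfigError
from .waveforms import DEFAULT_MAX_ORDER, WaveformSpec

__all__ = [
    "SystemConfig",
    "WaveformConfig",
    "AnalysisConfig",
    "EfficiencyConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemConfig(_Strict):
    eps_r_particle: float = Field(ge=1.0)
    sigma_particle: float = Field(default=0.0, ge=0.0)
    eps_r_medium: float = Field(ge=1.0)
    sigma_medium: float = Field(ge=0.0)
    radius: float = Field(gt=0.0)
    surface_conductance: float = Field(default=0.0, ge=0.0)

    def build(self) -> ParticleSystem:
        return ParticleSystem(
            particle=DielectricMaterial(self.eps_r_particle, self.sigma_particle),
            medium=DielectricMaterial(self.eps_r_medium, self.sigma_medium),
            radius=self.radius,
            surface_conductance=self.surface_conductance,
        )


class WaveformConfig(_Strict):
    shape: Literal["sine", "rectangular"] = "rectangular"
    v0: float = Field(default=1.0, gt=0.0)
    f0: float = Field(gt=0.0)
    max_order: int = Field(default=DEFAULT_MAX_ORDER, ge=1)
    bandwidth_limit: Optional[float] = Field(default=None, gt=0.0)
    rolloff: Literal["brickwall", "first_order"] = "brickwall"

    def build(self) -> WaveformSpec:
        return WaveformSpec(self.shape, self.v0, self.f0)


class AnalysisConfig(_Strict):
    field_gradient: float = Field(default=1.0, gt=0.0)
    comparison: Literal["equal-peak", "equal-rms"] = "equal-peak"


class EfficiencyConfig(_Strict):
    baseline_window: tuple[float, float] = (10.0, 55.0)
    eval_window: tuple[float, float] = (225.0, 245.0)
    schedule: tuple[float, float] = (70.0, 250.0)


class RunConfig(_Strict):
    system: SystemConfig
    waveform: WaveformConfig
    analysis: AnalysisConfig = AnalysisConfig()
    efficiency: EfficiencyConfig = EfficiencyConfig()
    seed: int = 0


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Read and validate a YAML run configuration.

    ``overrides`` is a nested dict of the same shape merged on top of
    the file contents (CLI flags). Raises :class:`ConfigError` with the
    offending field path on any validation failure.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError as e:
        raise ConfigError(f"config file not found: {path}") from e
    except yaml.YAMLError as e:
        raise ConfigError(f"config file {path} is not valid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    if overrides:
        raw = _merge(raw, overrides)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors()
        )
        raise ConfigError(f"invalid configuration in {path}: {locs}") from e


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        elif v is not None:
            out[k] = v
    return out
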