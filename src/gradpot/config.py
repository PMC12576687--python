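"""Run configuration: YAML schema, validation, conversion to domain objects.

A run config is a single YAML document (``schema_version: 1``) declaring the
start and target solutions, the pot, the gradient request, the pump hardware
and output options.  Unknown keys are rejected so typos fail loudly.  All
volumes are µl, times minutes, evaporation µl/h, flow µl/min — the same
single-unit policy used in every file the pipeline writes.

Example::

    schema_version: 1
    label: lysozyme
    start:
      components:
        - {name: NaCl, concentration: 8, unit: "%w/v"}
    target:
      components:
        - {name: NaCl, concentration: 3, unit: "%w/v"}
        - {name: lysozyme, concentration: 5, unit: mg/ml}
    pot: {volume_ul: 40, evaporation_ul_per_h: 0}
    gradient: {final_fraction: 0.95, duration_min: 40, mode: linear}
    pump: {syringe_volume_ml: 1}
    outputs: {sample_dt_min: 0.5}

Omitted sections take the documented defaults (40 µl pot with no
evaporation, 0–95% linear gradient, BD 1 ml syringe).  ``gradient.ticks``
defaults to the largest count that keeps every event at ≥ 10 pump quanta
(capped at 1000).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .planner import GradientSpec, default_tick_count
from .pump import PumpConfig, volume_per_microstep
from .reservoir import PotState
from .solutions import Component, Solution, canonical_unit

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "example_config_path",
    "EXAMPLE_NAMES",
]

#: Packaged worked protocols (see ``gradpot/examples/*.yaml``).
EXAMPLE_NAMES = ("lysozyme", "thermolysin", "alpha_lactalbumin")


class ConfigError(ValueError):
    """Configuration failed to parse or validate."""


class ComponentCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = Field(min_length=1)
    concentration: float = Field(ge=0)
    unit: str
    density_contribution: Optional[float] = Field(default=None, ge=0)

    @field_validator("unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        return canonical_unit(v)

    def to_domain(self) -> Component:
        return Component(self.name, self.concentration, self.unit, self.density_contribution)


class SolutionCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    components: list[ComponentCfg] = Field(default_factory=list)
    label: str = ""

    def to_domain(self, fallback_label: str = "") -> Solution:
        return Solution(
            tuple(c.to_domain() for c in self.components),
            label=self.label or fallback_label,
        )


class PotCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    volume_ul: float = Field(default=40.0, gt=0)
    evaporation_ul_per_h: float = Field(default=0.0, ge=0)


class GradientCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    final_fraction: float = Field(default=0.95, ge=0)
    duration_min: float = Field(default=40.0, gt=0)
    mode: Literal["linear", "equal_volume", "linear_fixed_quantum"] = "linear"
    ticks: Optional[int] = Field(default=None, ge=1, le=100000)

    @field_validator("final_fraction")
    @classmethod
    def _f(cls, v: float) -> float:
        if v >= 1.0:
            raise ValueError(
                "final_fraction must be < 1 (full exchange needs infinite volume)"
            )
        return v


class PumpCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    syringe_volume_ml: float = Field(default=1.0, gt=0)
    syringe_inner_diameter_mm: float = Field(default=4.78, gt=0)
    lead_mm: float = Field(default=0.8, gt=0)
    steps_per_rev: int = Field(default=200, gt=0)
    microstepping: int = Field(default=16, gt=0)
    min_injection_ul: Optional[float] = Field(default=None, gt=0)
    max_flow_ul_min: float = Field(default=1000.0, gt=0)
    label: str = "BD 1 ml"

    def to_domain(self) -> PumpConfig:
        return PumpConfig(
            syringe_volume=self.syringe_volume_ml,
            syringe_inner_diameter=self.syringe_inner_diameter_mm,
            lead=self.lead_mm,
            steps_per_rev=self.steps_per_rev,
            microstepping=self.microstepping,
            min_injection=self.min_injection_ul,
            max_flow=self.max_flow_ul_min,
            label=self.label,
        )


class OutputsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_dt_min: float = Field(default=0.5, gt=0)


class RunConfig(BaseModel):
    """Validated top-level configuration for one gradient run."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    label: str = ""
    start: SolutionCfg
    target: SolutionCfg
    pot: PotCfg = Field(default_factory=PotCfg)
    gradient: GradientCfg = Field(default_factory=GradientCfg)
    pump: PumpCfg = Field(default_factory=PumpCfg)
    outputs: OutputsCfg = Field(default_factory=OutputsCfg)
    seed: Optional[int] = None

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v != 1:
            raise ValueError(f"unsupported schema_version {v}; this release reads version 1")
        return v

    # -- domain conversion --------------------------------------------------

    def start_solution(self) -> Solution:
        return self.start.to_domain("start")

    def target_solution(self) -> Solution:
        return self.target.to_domain("target")

    def pot_state(self) -> PotState:
        return PotState(
            volume=self.pot.volume_ul,
            composition=self.start_solution(),
            evaporation_rate=self.pot.evaporation_ul_per_h,
        )

    def pump_config(self) -> PumpConfig:
        return self.pump.to_domain()

    def resolved_ticks(self) -> int:
        if self.gradient.ticks is not None:
            return self.gradient.ticks
        return default_tick_count(
            self.pot.volume_ul,
            self.gradient.final_fraction,
            volume_per_microstep(self.pump_config()),
        )

    def gradient_spec(self) -> GradientSpec:
        start = self.start_solution()
        target = self.target_solution()
        if start.same_composition(target):
            raise ConfigError(
                "start and target solutions are identical: nothing to exchange"
            )
        return GradientSpec(
            start=start,
            target=target,
            final_fraction=self.gradient.final_fraction,
            duration=self.gradient.duration_min,
            mode=self.gradient.mode,
            ticks=self.resolved_ticks(),
            pot=self.pot_state(),
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigError` with the offending field path on any parse or
    validation failure.
    """
    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"{p}: {exc}") from exc


def example_config_path(name: str) -> Path:
    """Path to a packaged example config (one of :data:`EXAMPLE_NAMES`)."""
    if name not in EXAMPLE_NAMES:
        raise KeyError(f"unknown example {name!r}; available: {EXAMPLE_NAMES}")
    return Path(__file__).parent / "examples" / f"{name}.yaml"
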