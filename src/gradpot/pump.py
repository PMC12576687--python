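"""Syringe-pump kinematics: microstep quantization and a virtual executor.

A stepper motor turning a lead screw translates the syringe plunger, so the
smallest deliverable volume is one microstep's worth of plunger travel:

    q = π (d/2)² · lead / (steps_per_rev · microstepping)

With a BD 1 ml syringe (inner diameter 4.78 mm), an 0.8 mm lead screw and a
200-step motor at 16× microstepping this is about 4.5 nl; finer microstepping
or a narrower syringe brings it to the few-nl scale.  These hardware defaults
are documented vendor geometry, overridable per config — only the resulting
resolution matters to the planner.

Quantization uses a carry accumulator on the *cumulative* volume: after every
event the delivered total differs from the ideal total by at most half a
quantum, so rounding errors never build up over a long schedule.  Inflow and
outflow pumps receive identical step counts for constant-volume events, so
quantization cannot change the pot volume.

A "virtual pump" converts step commands back into exchange events and runs
them through the reservoir simulator, making the whole pipeline testable with
no hardware attached; a serial/motor adapter can consume the same command
stream (see :func:`write_command_script`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import pandas as pd

from .planner import Schedule
from .reservoir import (
    EventModel,
    ExchangeEvent,
    PotState,
    SimTrace,
    execute_schedule,
)

__all__ = [
    "PumpConfig",
    "StepCommand",
    "PumpConfigError",
    "QuantizationWarning",
    "volume_per_microstep",
    "quantize",
    "check_feasibility",
    "FeasibilityReport",
    "run_virtual",
    "write_commands_csv",
    "write_command_script",
    "BD_1ML",
    "BD_3ML",
]


class PumpConfigError(ValueError):
    """A pump parameter is nonpositive or inconsistent."""


class QuantizationWarning(UserWarning):
    """An event was too small to step and was merged into the carry."""


@dataclass(frozen=True)
class PumpConfig:
    """Syringe-pump geometry and limits.

    Attributes
    ----------
    syringe_volume : float
        Syringe capacity, ml (sets the total deliverable volume).
    syringe_inner_diameter : float
        Barrel inner diameter, mm.
    lead : float
        Lead-screw advance per revolution, mm.
    steps_per_rev : int
        Full steps per motor revolution.
    microstepping : int
        Microsteps per full step.
    min_injection : float | None
        Smallest injection honoured, µl.  Defaults to the derived microstep
        volume; may be raised (e.g. to 0.002 µl) to enforce a coarser floor.
    max_flow : float
        Maximum sustained flow, µl/min.
    """

    syringe_volume: float = 1.0
    syringe_inner_diameter: float = 4.78
    lead: float = 0.8
    steps_per_rev: int = 200
    microstepping: int = 16
    min_injection: float | None = None
    max_flow: float = 1000.0
    label: str = "BD 1 ml"

    def __post_init__(self) -> None:
        for name in (
            "syringe_volume",
            "syringe_inner_diameter",
            "lead",
            "steps_per_rev",
            "microstepping",
            "max_flow",
        ):
            if getattr(self, name) <= 0:
                raise PumpConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        q = volume_per_microstep(self)
        if self.min_injection is None:
            object.__setattr__(self, "min_injection", q)
        elif self.min_injection < q - 1e-15:
            raise PumpConfigError(
                f"min_injection ({self.min_injection} µl) below one microstep ({q:.4g} µl)"
            )

    @property
    def capacity_ul(self) -> float:
        return self.syringe_volume * 1000.0


def volume_per_microstep(cfg: PumpConfig) -> float:
    """Volume of one microstep, µl: π·(d/2)²·lead / (steps_per_rev·microstepping).

    mm³ and µl coincide, so no unit factor is needed.
    """
    if cfg.syringe_inner_diameter <= 0 or cfg.lead <= 0:
        raise PumpConfigError("syringe diameter and lead must be > 0")
    if cfg.steps_per_rev <= 0 or cfg.microstepping <= 0:
        raise PumpConfigError("steps_per_rev and microstepping must be > 0")
    area = math.pi * (cfg.syringe_inner_diameter / 2.0) ** 2  # mm²
    return area * cfg.lead / (cfg.steps_per_rev * cfg.microstepping)


#: Documented defaults for common BD syringes on a 0.8 mm lead screw,
#: 200 steps/rev, 16× microstepping.
BD_1ML = PumpConfig()
BD_3ML = PumpConfig(syringe_volume=3.0, syringe_inner_diameter=8.66, label="BD 3 ml")


@dataclass(frozen=True)
class StepCommand:
    """One motor command: ``microsteps`` microsteps on ``pump_id`` at ``time`` min."""

    time: float
    pump_id: Literal["inflow", "outflow"]
    microsteps: int

    def __post_init__(self) -> None:
        if self.microsteps < 0:
            raise ValueError("microsteps must be >= 0")
        if self.pump_id not in ("inflow", "outflow"):
            raise ValueError(f"pump_id must be 'inflow' or 'outflow', got {self.pump_id!r}")


def quantize(
    schedule: Schedule, cfg: PumpConfig
) -> tuple[list[StepCommand], Schedule]:
    """Round a schedule onto the pump's microstep grid with a carry accumulator.

    The step count for event ``k`` is chosen so the cumulative delivered
    volume equals the ideal cumulative volume rounded to the nearest multiple
    of the quantum ``q`` (with ``min_injection`` enforcing a coarser effective
    quantum when set): ``|cum_quantized − cum_ideal| ≤ q_eff/2`` after every
    event.  Identical counts go to inflow and outflow pumps when the event
    volumes match, so the pot volume is preserved exactly.

    Events that round to zero steps are merged into the carry (a
    :class:`QuantizationWarning` is issued); the volume is recovered by later
    events, never silently lost.
    """
    q = volume_per_microstep(cfg)
    q_eff = max(q, cfg.min_injection or q)
    steps_per_unit = max(1, round(q_eff / q))
    q_eff = steps_per_unit * q  # effective quantum is an integer step count

    commands: list[StepCommand] = []
    new_events: list[ExchangeEvent] = []
    cum_in_ideal = cum_in_steps = 0.0
    cum_out_ideal = cum_out_steps = 0.0
    zero_events = 0
    for e in schedule.events:
        cum_in_ideal += e.inflow_volume
        cum_out_ideal += e.outflow_volume
        in_units = round(cum_in_ideal / q_eff)
        out_units = round(cum_out_ideal / q_eff)
        in_steps = in_units * steps_per_unit - cum_in_steps
        out_steps = out_units * steps_per_unit - cum_out_steps
        cum_in_steps += in_steps
        cum_out_steps += out_steps
        if in_steps == 0 and e.inflow_volume > 0:
            zero_events += 1
        commands.append(StepCommand(e.time, "inflow", int(in_steps)))
        commands.append(StepCommand(e.time, "outflow", int(out_steps)))
        new_events.append(
            replace(e, inflow_volume=in_steps * q, outflow_volume=out_steps * q)
        )
    if zero_events:
        warnings.warn(
            f"{zero_events} event(s) below one quantum ({q_eff:.4g} µl) were merged "
            "into the carry; volume is delivered by subsequent events",
            QuantizationWarning,
            stacklevel=2,
        )
    quantized = Schedule(
        tuple(new_events), schedule.ideal_volumes, provenance=schedule.provenance
    )
    return commands, quantized


@dataclass(frozen=True)
class FeasibilityReport:
    """Hardware feasibility check result; ``violations`` is empty iff feasible."""

    violations: tuple[str, ...]
    total_inflow: float
    max_implied_flow: float
    quantum: float

    @property
    def feasible(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = "feasible" if self.feasible else "INFEASIBLE"
        body = "".join(f"\n  - {v}" for v in self.violations)
        return (
            f"{head}: total inflow {self.total_inflow:.2f} µl, "
            f"peak implied flow {self.max_implied_flow:.3g} µl/min, "
            f"quantum {self.quantum * 1000:.3g} nl{body}"
        )


def check_feasibility(
    schedule: Schedule, cfg: PumpConfig, pot: PotState
) -> FeasibilityReport:
    """Check a (quantized or ideal) schedule against pump and pot limits.

    Flags: events that quantize to zero steps; implied flow (event volume over
    the preceding inter-event gap) above ``max_flow``; total inflow above the
    syringe capacity; any single withdrawal larger than the pot volume.
    """
    q = volume_per_microstep(cfg)
    violations: list[str] = []
    total_in = schedule.total_inflow
    max_flow_seen = 0.0
    prev_t = 0.0
    for i, e in enumerate(schedule.events):
        if 0 < e.inflow_volume < q * 0.5:
            violations.append(
                f"event {i} at t={e.time:g} min: volume {e.inflow_volume:.4g} µl "
                f"is below one microstep ({q:.4g} µl) and would emit zero steps"
            )
        gap = e.time - prev_t
        if gap > 0:
            flow = e.inflow_volume / gap
            max_flow_seen = max(max_flow_seen, flow)
            if flow > cfg.max_flow:
                violations.append(
                    f"event {i} at t={e.time:g} min: implied flow {flow:.3g} µl/min "
                    f"exceeds max_flow {cfg.max_flow:g} µl/min"
                )
        if e.outflow_volume > pot.volume:
            violations.append(
                f"event {i} at t={e.time:g} min: withdrawal {e.outflow_volume:.4g} µl "
                f"exceeds pot volume {pot.volume:g} µl"
            )
        prev_t = e.time
    if total_in > cfg.capacity_ul:
        violations.append(
            f"total inflow {total_in:.2f} µl exceeds syringe capacity "
            f"{cfg.capacity_ul:g} µl ({cfg.label})"
        )
    return FeasibilityReport(
        violations=tuple(violations),
        total_inflow=total_in,
        max_implied_flow=max_flow_seen,
        quantum=q,
    )


def run_virtual(
    commands: Sequence[StepCommand],
    cfg: PumpConfig,
    pot: PotState,
    inflow_solution=None,
    sample_dt: float = 1.0,
    event_model: EventModel = "simultaneous",
) -> SimTrace:
    """Execute step commands on the software twin of the pump pair.

    Paired inflow/outflow commands sharing a timestamp form a single
    simultaneous exchange event.  ``inflow_solution`` defaults to pure water;
    pass the gradient's target solution for a realistic run.
    """
    from .solutions import Solution

    if inflow_solution is None:
        inflow_solution = Solution.water()
    q = volume_per_microstep(cfg)
    by_time: dict[float, dict[str, int]] = {}
    last = {"inflow": -math.inf, "outflow": -math.inf}
    for cmd in commands:
        if cmd.time < last[cmd.pump_id]:
            raise ValueError("commands must be time-ordered per pump")
        last[cmd.pump_id] = cmd.time
        slot = by_time.setdefault(cmd.time, {"inflow": 0, "outflow": 0})
        slot[cmd.pump_id] += cmd.microsteps
    events = tuple(
        ExchangeEvent(
            time=t,
            inflow_volume=slot["inflow"] * q,
            outflow_volume=slot["outflow"] * q,
            inflow_solution=inflow_solution,
        )
        for t, slot in sorted(by_time.items())
    )
    if not events:
        events = ()
    return execute_schedule(pot, events, sample_dt=sample_dt, event_model=event_model)


# ---------------------------------------------------------------------------
# command output formats


def write_commands_csv(commands: Iterable[StepCommand], path) -> None:
    """CSV with columns time_min, pump_id, microsteps."""
    df = pd.DataFrame(
        [
            {"time_min": c.time, "pump_id": c.pump_id, "microsteps": c.microsteps}
            for c in commands
        ],
        columns=["time_min", "pump_id", "microsteps"],
    )
    df.to_csv(path, index=False, lineterminator="\n")


def write_command_script(commands: Iterable[StepCommand], path) -> None:
    """Plain-text firmware script: one ``<t_ms> <pump> <steps>`` line per command.

    Times are integer milliseconds; the adapter driving real motors replays
    the lines in order.
    """
    with open(path, "w") as fh:
        for c in commands:
            fh.write(f"{round(c.time * 60000)} {c.pump_id} {c.microsteps}\n")
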