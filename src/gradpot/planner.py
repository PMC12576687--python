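"""Schedule synthesis for concentration gradients, and verification.

Because simultaneous exchange is exponential in delivered volume, reaching an
exchange fraction ``f`` always costs a total inflow of ``V·ln(1/(1−f))``
regardless of how the delivery is chopped into events — the *total-volume
law*.  For the standard 40 µl pot and ``f = 0.95`` this is ``40·ln 20 ≈
119.83 µl``; ``f = 1`` would cost infinite volume, which is why gradients
stop short of 100% and are optionally re-run.

Two gradient modes are planned, both with ``n`` events at uniform time ticks
``t_k = kT/n`` (first event at ``T/n``, so the crystal starts in pure start
solution):

linear
    ``x(t_k) = f·k/n`` — the exchange fraction rises linearly in time.  The
    per-event volumes ``ΔV_k = V·ln[(1 − f(k−1)/n) / (1 − f·k/n)]`` grow
    toward the end of the gradient (each increment fights a pot that is
    already mostly target solution).
equal_volume
    Every event delivers the same ``ΔV = (V/n)·ln(1/(1−f))``; the trajectory
    is exponential-shaped, ``x(t_k) = 1 − (1−f)^{k/n}``, steepest at the
    start.

A ``linear_fixed_quantum`` variant realizes the linear trajectory with
constant-volume events at non-uniform times instead; both readings satisfy
the same trajectory and the variable-volume form is the default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .reservoir import EventModel, ExchangeEvent, PotState, SimTrace, execute_schedule
from .solutions import Solution, mix

__all__ = [
    "GradientMode",
    "InfeasibleGradientError",
    "GradientSpec",
    "Schedule",
    "plan",
    "plan_linear",
    "plan_equal_volume",
    "plan_linear_fixed_quantum",
    "rerun_composition",
    "verify_schedule",
    "VerificationReport",
    "exposure_report",
    "ExposureMetrics",
    "default_tick_count",
]

GradientMode = Literal["linear", "equal_volume", "linear_fixed_quantum"]


class InfeasibleGradientError(ValueError):
    """The requested gradient cannot be realized (e.g. f >= 1)."""


@dataclass(frozen=True)
class GradientSpec:
    """A requested gradient: end-member solutions, extent, duration, shape.

    Attributes
    ----------
    start, target : Solution
        End members of the mixing line.
    final_fraction : float
        Target exchange fraction ``f`` in ``[0, 1)``; 0.95 and 0.98 are the
        usual working values.
    duration : float
        Gradient length ``T`` in minutes.
    mode : str
        ``linear`` | ``equal_volume`` | ``linear_fixed_quantum``.
    ticks : int
        Number of discrete exchange events ``n``.
    pot : PotState
        Pot the gradient will run in (volume and evaporation rate).
    """

    start: Solution
    target: Solution
    final_fraction: float
    duration: float
    mode: GradientMode
    ticks: int
    pot: PotState

    def __post_init__(self) -> None:
        if not 0.0 <= self.final_fraction < 1.0:
            raise InfeasibleGradientError(
                f"final fraction must lie in [0, 1); got {self.final_fraction} "
                "(x = 1 needs infinite exchanged volume)"
            )
        if self.duration <= 0:
            raise ValueError("gradient duration must be > 0 min")
        if self.ticks < 1:
            raise ValueError("ticks must be >= 1")
        if self.mode not in ("linear", "equal_volume", "linear_fixed_quantum"):
            raise ValueError(f"unknown gradient mode {self.mode!r}")

    def requested_trajectory(self) -> tuple[np.ndarray, np.ndarray]:
        """The ideal ``(t_k, x_k)`` arrays the planner aims for (E = 0)."""
        f, n, t_total = self.final_fraction, self.ticks, self.duration
        k = np.arange(1, n + 1, dtype=float)
        if self.mode == "linear":
            return k * t_total / n, f * k / n
        x = 1.0 - (1.0 - f) ** (k / n)
        if self.mode == "equal_volume":
            return k * t_total / n, x
        # linear_fixed_quantum: constant-volume events placed so that x rises
        # linearly in time, i.e. x(t_k) = f·t_k/T at the warped tick times
        t = t_total * x / f if f > 0 else k * t_total / n
        return t, x


@dataclass(frozen=True)
class Schedule:
    """An ordered list of exchange events plus the unquantized ideal volumes.

    ``ideal_volumes`` records what the planner asked for before any pump
    quantization; after :func:`gradpot.pump.quantize` the event volumes are
    integer multiples of the microstep quantum while ``ideal_volumes`` is
    preserved for error accounting.
    """

    events: tuple[ExchangeEvent, ...]
    ideal_volumes: tuple[float, ...]
    provenance: GradientSpec | None = None

    def __post_init__(self) -> None:
        if len(self.events) != len(self.ideal_volumes):
            raise ValueError("one ideal volume per event required")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    @property
    def total_inflow(self) -> float:
        return sum(e.inflow_volume for e in self.events)

    @property
    def total_outflow(self) -> float:
        return sum(e.outflow_volume for e in self.events)

    @property
    def total_ideal(self) -> float:
        return sum(self.ideal_volumes)

    def __len__(self) -> int:
        return len(self.events)

    # -- serialization ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        cum = 0.0
        for i, e in enumerate(self.events):
            cum += e.inflow_volume
            rows.append(
                {
                    "event_index": i,
                    "time_min": e.time,
                    "inflow_ul": e.inflow_volume,
                    "outflow_ul": e.outflow_volume,
                    "cumulative_ul": cum,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["event_index", "time_min", "inflow_ul", "outflow_ul", "cumulative_ul"],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    def to_json_obj(self) -> dict:
        obj = {
            "events": [
                {
                    "time_min": e.time,
                    "inflow_ul": e.inflow_volume,
                    "outflow_ul": e.outflow_volume,
                    "inflow_solution": e.inflow_solution.to_json_obj(),
                }
                for e in self.events
            ],
            "ideal_volumes_ul": list(self.ideal_volumes),
            "total_inflow_ul": self.total_inflow,
            "total_outflow_ul": self.total_outflow,
        }
        if self.provenance is not None:
            p = self.provenance
            obj["provenance"] = {
                "final_fraction": p.final_fraction,
                "duration_min": p.duration,
                "mode": p.mode,
                "ticks": p.ticks,
                "pot_volume_ul": p.pot.volume,
                "evaporation_ul_per_h": p.pot.evaporation_rate,
                "start": p.start.to_json_obj(),
                "target": p.target.to_json_obj(),
            }
        return obj

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "Schedule":
        from .solutions import Component

        with open(path) as fh:
            obj = json.load(fh)

        def sol(items, label=""):
            return Solution(
                tuple(
                    Component(
                        d["name"],
                        d["concentration"],
                        d["unit"],
                        d.get("density_contribution"),
                    )
                    for d in items
                ),
                label=label,
            )

        events = tuple(
            ExchangeEvent(
                time=e["time_min"],
                inflow_volume=e["inflow_ul"],
                outflow_volume=e["outflow_ul"],
                inflow_solution=sol(e["inflow_solution"]),
            )
            for e in obj["events"]
        )
        prov = None
        if "provenance" in obj:
            p = obj["provenance"]
            prov = GradientSpec(
                start=sol(p["start"], "start"),
                target=sol(p["target"], "target"),
                final_fraction=p["final_fraction"],
                duration=p["duration_min"],
                mode=p["mode"],
                ticks=p["ticks"],
                pot=PotState(
                    volume=p["pot_volume_ul"],
                    composition=sol(p["start"], "start"),
                    evaporation_rate=p["evaporation_ul_per_h"],
                ),
            )
        return cls(events, tuple(obj["ideal_volumes_ul"]), provenance=prov)


# ---------------------------------------------------------------------------
# planners


def total_volume_required(pot_volume: float, final_fraction: float) -> float:
    """Total inflow needed to reach ``f`` by simultaneous exchange: V·ln(1/(1−f))."""
    if not 0.0 <= final_fraction < 1.0:
        raise InfeasibleGradientError(f"final fraction {final_fraction} not in [0, 1)")
    return pot_volume * math.log(1.0 / (1.0 - final_fraction))


def _build(spec: GradientSpec, times, volumes) -> Schedule:
    events = tuple(
        ExchangeEvent(
            time=float(t),
            inflow_volume=float(v),
            outflow_volume=float(v),
            inflow_solution=spec.target,
        )
        for t, v in zip(times, volumes)
    )
    return Schedule(events, tuple(float(v) for v in volumes), provenance=spec)


def plan_linear(spec: GradientSpec) -> Schedule:
    """Events at uniform ticks whose volumes make x(t_k) = f·k/n exactly (E = 0).

    ``ΔV_k = V·ln[(1 − f(k−1)/n)/(1 − f·k/n)]``; volumes strictly increase
    with ``k`` and sum to ``V·ln(1/(1−f))``.  ``f = 0`` yields an empty
    schedule.
    """
    f, n, v = spec.final_fraction, spec.ticks, spec.pot.volume
    if f == 0.0:
        return Schedule((), (), provenance=spec)
    k = np.arange(1, n + 1, dtype=float)
    volumes = v * np.log((1.0 - f * (k - 1) / n) / (1.0 - f * k / n))
    times = k * spec.duration / n
    return _build(spec, times, volumes)


def plan_equal_volume(spec: GradientSpec) -> Schedule:
    """Events at uniform ticks, each delivering ``(V/n)·ln(1/(1−f))``."""
    f, n, v = spec.final_fraction, spec.ticks, spec.pot.volume
    if f == 0.0:
        return Schedule((), (), provenance=spec)
    per_event = total_volume_required(v, f) / n
    k = np.arange(1, n + 1, dtype=float)
    return _build(spec, k * spec.duration / n, np.full(n, per_event))


def plan_linear_fixed_quantum(spec: GradientSpec) -> Schedule:
    """Linear-in-time trajectory realized with equal volumes at non-uniform times.

    The k-th event (volume ``q = (V/n)·ln(1/(1−f))``) fires when the linear
    ramp calls for ``x = 1 − (1−f)^{k/n}``, i.e. at
    ``t_k = (T/f)·(1 − (1−f)^{k/n})``.
    """
    f, n, v = spec.final_fraction, spec.ticks, spec.pot.volume
    if f == 0.0:
        return Schedule((), (), provenance=spec)
    per_event = total_volume_required(v, f) / n
    k = np.arange(1, n + 1, dtype=float)
    times = spec.duration * (1.0 - (1.0 - f) ** (k / n)) / f
    return _build(spec, times, np.full(n, per_event))


_PLANNERS = {
    "linear": plan_linear,
    "equal_volume": plan_equal_volume,
    "linear_fixed_quantum": plan_linear_fixed_quantum,
}


def plan(spec: GradientSpec) -> Schedule:
    """Dispatch to the planner for ``spec.mode``."""
    return _PLANNERS[spec.mode](spec)


def default_tick_count(
    pot_volume: float, final_fraction: float, quantum: float, cap: int = 1000
) -> int:
    """Largest tick count keeping every event at least 10 pump quanta.

    More ticks mean a smoother gradient but smaller events; below ~10 quanta
    per event the stepper quantization error per event exceeds ~10%.  The
    smallest planned event is the first linear-mode event,
    ``V·ln(1/(1 − f/n)) ≈ V·f/n``, so the bound is found by scanning down
    from ``cap``.  Returns at least 1.
    """
    if final_fraction == 0.0:
        return 1
    floor = 10.0 * quantum
    for n in range(cap, 0, -1):
        first = pot_volume * math.log(1.0 / (1.0 - final_fraction / n))
        if first >= floor:
            return n
    return 1


def rerun_composition(f1: float, f2: float) -> float:
    """Combined exchange fraction after running a second gradient: 1 − (1−f1)(1−f2).

    Running a 0–95% gradient twice leaves only 0.05² = 0.25% of the original
    solution, i.e. a combined fraction of 0.9975.
    """
    for f in (f1, f2):
        if not 0.0 <= f < 1.0:
            raise InfeasibleGradientError(f"fraction {f} not in [0, 1)")
    return 1.0 - (1.0 - f1) * (1.0 - f2)


# ---------------------------------------------------------------------------
# verification and exposure metrics


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of simulating a schedule against its requested trajectory."""

    max_x_deviation: float
    final_composition_deviation: dict[str, float]
    final_x: float
    requested_final_x: float
    tolerance: float
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        comp = ", ".join(
            f"{k}: {v:.3g}" for k, v in self.final_composition_deviation.items()
        )
        return (
            f"[{status}] max |x_sim - x_req| = {self.max_x_deviation:.3g} "
            f"(tol {self.tolerance:g}); final x = {self.final_x:.6f} "
            f"(requested {self.requested_final_x:.6f}); "
            f"final composition deviation: {comp or 'none'}"
        )


def verify_schedule(
    schedule: Schedule,
    spec: GradientSpec,
    tol: float,
    event_model: EventModel = "simultaneous",
) -> VerificationReport:
    """Execute ``schedule`` in the simulator and compare with the request.

    Uses the pot's evaporation rate, so an uncompensated-evaporation deviation
    shows up here rather than being silently absorbed.  Passes iff the maximum
    ``|x_sim(t_k) − x_requested(t_k)|`` over the ticks is ≤ ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    t_req, x_req = spec.requested_trajectory()
    if len(schedule) == 0:
        final = spec.pot.composition
        dev = {
            f"{c.name} ({c.unit})": abs(final[c.name] - mix(spec.start, spec.target, 0.0)[c.name])
            for c in spec.start.components
        }
        return VerificationReport(0.0, dev, spec.pot.x, 0.0, tol, True)
    trace = execute_schedule(
        spec.pot, schedule, sample_dt=max(spec.duration, 1e-6), event_model=event_model
    )
    x_sim = np.interp(t_req + spec.pot.time, trace.times, trace.x)
    max_dev = float(np.max(np.abs(x_sim - x_req)))
    ideal_final = mix(spec.start, spec.target, spec.final_fraction)
    final = trace.final_state(spec.pot.evaporation_rate).composition
    names = {c.name: c.unit for c in ideal_final.components}
    for c in final.components:
        names.setdefault(c.name, c.unit)
    comp_dev = {
        f"{name} ({unit})": abs(final[name] - ideal_final[name])
        for name, unit in sorted(names.items())
    }
    return VerificationReport(
        max_x_deviation=max_dev,
        final_composition_deviation=comp_dev,
        final_x=float(trace.x[-1]),
        requested_final_x=float(x_req[-1]),
        tolerance=tol,
        passed=max_dev <= tol,
    )


@dataclass(frozen=True)
class ExposureMetrics:
    """Rate-of-change summary of what the crystal experienced.

    ``max_dx_dt`` is the steepest sampled change of exchange fraction per
    minute (finite differences between consecutive samples, so the value for
    a discrete schedule depends on the sampling interval — a burst looks
    steeper the finer you sample).  ``t_half`` / ``t_95`` are the times at
    which the trace first reaches 50% and 95% of its final exchange fraction.
    """

    max_dx_dt: float
    max_dc_dt: dict[str, float]
    t_half: float
    t_95: float


class UndefinedDerivativeError(ValueError):
    """A rate metric was requested on a trace with fewer than two samples."""


def exposure_report(trace: SimTrace, final_fraction: float | None = None) -> ExposureMetrics:
    """Finite-difference exposure metrics from a simulated trace.

    ``final_fraction`` defaults to the trace's final x; thresholds for
    ``t_half``/``t_95`` are 0.5 and 0.95 of that value.
    """
    if len(trace) < 2:
        raise UndefinedDerivativeError("need at least two samples to form a rate")
    dt = np.diff(trace.times)
    good = dt > 0
    dx = np.abs(np.diff(trace.x))[good] / dt[good]
    max_dx = float(dx.max()) if dx.size else 0.0
    max_dc = {}
    for (name, unit), series in sorted(trace.concentrations.items()):
        dc = np.abs(np.diff(series))[good] / dt[good]
        max_dc[f"{name} ({unit})"] = float(dc.max()) if dc.size else 0.0
    f = trace.x[-1] if final_fraction is None else final_fraction

    def first_reach(level: float) -> float:
        if level <= trace.x[0]:
            return float(trace.times[0])
        idx = np.nonzero(trace.x >= level - 1e-15)[0]
        if idx.size == 0:
            return math.inf
        i = idx[0]
        if i == 0 or trace.x[i] == trace.x[i - 1]:
            return float(trace.times[i])
        # linear interpolation within the bracketing interval
        t0, t1 = trace.times[i - 1], trace.times[i]
        x0, x1 = trace.x[i - 1], trace.x[i]
        return float(t0 + (level - x0) / (x1 - x0) * (t1 - t0))

    return ExposureMetrics(
        max_dx_dt=max_dx,
        max_dc_dt=max_dc,
        t_half=first_reach(0.5 * f),
        t_95=first_reach(0.95 * f),
    )
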