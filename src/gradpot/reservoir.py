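"""Well-mixed pot simulation: exchange events, continuous flow, evaporation.

The pot (an inverted PCR-tube cap, typically 40 µl) is treated as a
continuously stirred tank: composition is spatially uniform at all times, so
simultaneous inflow/outflow at matched rates ``Q`` obeys the first-order law

.. math::

    \\frac{dx}{dt} = \\frac{Q}{V} (1 - x),

with ``x`` the fraction of pot fluid that has been delivered by the inflow
pump.  Exchanging one pot volume therefore reaches only ``x = 1 - e^{-1} ≈
0.632``, which is why finite gradients stop at e.g. 95 or 98%.

Two event models are provided for a discrete burst of volume ``ΔV``:

``simultaneous`` (default)
    In/out flow run together during the burst, giving the exact exponential
    update ``x ← 1 - (1 - x) e^{-ΔV/V}``.  This makes discrete schedules
    refinement-invariant and consistent with the continuous ODE.
``sequential``
    Withdraw ``ΔV`` then add ``ΔV``, giving the lever update
    ``x ← 1 - (1 - x)(1 - ΔV/V)``.

Evaporation removes solvent only (rate ``E`` in µl/h, converted to µl/min
internally): solutes are nonvolatile, so every concentration scales as
``V0/V(t)`` while the solute mass ``V·c`` is conserved.

Units: volumes in µl, time in minutes, flow in µl/min throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .solutions import Component, Solution

__all__ = [
    "EventModel",
    "PotEmptiedError",
    "PotState",
    "ExchangeEvent",
    "SimTrace",
    "apply_event",
    "evaporate",
    "simulate_continuous",
    "execute_schedule",
]

EventModel = Literal["simultaneous", "sequential"]

#: RK4 step ceiling in minutes; keeps the analytic test cases at ~1e-13.
MAX_ODE_STEP_MIN = 0.1


class PotEmptiedError(RuntimeError):
    """The pot volume reached zero (withdrawal or evaporation exceeded contents)."""


@dataclass(frozen=True)
class PotState:
    """Instantaneous state of the crystal pot.

    Attributes
    ----------
    volume : float
        Current liquid volume, µl (> 0).
    composition : Solution
        Current solute concentrations.
    evaporation_rate : float
        Solvent loss rate, µl/h (≥ 0).  6 µl/h is typical for an open pot at
        30–40% relative humidity; a cover reduces it to about 1 µl/h.
    x : float
        Pump-delivered fluid fraction in [0, 1].  Updated exactly by exchange
        events; unchanged by evaporation.  Composition is the authoritative
        record — use :func:`gradpot.solutions.exchange_fraction_of` for a
        composition-based readout.
    time : float
        Minutes since the start of the run.
    """

    volume: float
    composition: Solution
    evaporation_rate: float = 0.0
    x: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"pot volume must be > 0 µl, got {self.volume}")
        if self.evaporation_rate < 0:
            raise ValueError("evaporation rate must be >= 0 µl/h")
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("x must lie in [0, 1]")
        if self.time < 0:
            raise ValueError("time must be >= 0 min")


@dataclass(frozen=True)
class ExchangeEvent:
    """A timed burst of simultaneous withdrawal and injection.

    ``inflow_volume`` and ``outflow_volume`` are usually equal (constant-volume
    exchange); unequal volumes are permitted and change the pot volume by the
    difference.
    """

    time: float
    inflow_volume: float
    outflow_volume: float
    inflow_solution: Solution

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0 min")
        if self.inflow_volume < 0 or self.outflow_volume < 0:
            raise ValueError("event volumes must be >= 0 µl")


@dataclass(frozen=True)
class SimTrace:
    """Sampled time series of the pot state.

    Parallel arrays: ``times`` (min), ``volumes`` (µl), ``x`` and one
    concentration series per component key ``(name, unit)``.
    """

    times: np.ndarray
    volumes: np.ndarray
    x: np.ndarray
    concentrations: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.times)
        if len(self.volumes) != n or len(self.x) != n:
            raise ValueError("trace series lengths differ")
        for key, series in self.concentrations.items():
            if len(series) != n:
                raise ValueError(f"trace series lengths differ for component {key}")
            if np.any(series < -1e-12):
                raise ValueError(f"negative concentration in trace for {key}")

    def __len__(self) -> int:
        return len(self.times)

    def final_state(self, evaporation_rate: float = 0.0) -> PotState:
        comps = tuple(
            Component(name, float(series[-1]), unit)
            for (name, unit), series in self.concentrations.items()
        )
        return PotState(
            volume=float(self.volumes[-1]),
            composition=Solution(comps),
            evaporation_rate=evaporation_rate,
            x=float(self.x[-1]),
            time=float(self.times[-1]),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_min": self.times, "volume_ul": self.volumes, "x": self.x}
        for (name, unit), series in sorted(self.concentrations.items()):
            cols[f"{name}_{unit}"] = series
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Write the RFC 4180 trace table (header row, dot decimal)."""
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    def value_at(self, t: float) -> tuple[float, float]:
        """Linearly interpolated ``(volume, x)`` at time ``t``."""
        v = float(np.interp(t, self.times, self.volumes))
        x = float(np.interp(t, self.times, self.x))
        return v, x


# ---------------------------------------------------------------------------
# discrete events


def evaporate(state: PotState, dt: float) -> PotState:
    """Advance ``dt`` minutes with no flow: solvent evaporates, solutes stay.

    Exact update: volume falls linearly, each concentration scales by
    ``V0 / V(t)`` so the solute mass ``V·c`` is conserved; ``x`` is unchanged.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0 or state.evaporation_rate == 0:
        return replace(state, time=state.time + dt)
    v1 = state.volume - (state.evaporation_rate / 60.0) * dt
    if v1 <= 0:
        raise PotEmptiedError(
            f"evaporation emptied the pot at t <= {state.time + dt:.2f} min "
            f"(V0 = {state.volume:.2f} µl, E = {state.evaporation_rate} µl/h)"
        )
    factor = state.volume / v1
    comps = tuple(
        replace(c, concentration=c.concentration * factor)
        for c in state.composition.components
    )
    return replace(
        state,
        volume=v1,
        composition=replace(state.composition, components=comps),
        time=state.time + dt,
    )


def apply_event(
    state: PotState,
    event: ExchangeEvent,
    event_model: EventModel = "simultaneous",
) -> PotState:
    """Apply one exchange event instantaneously (evaporation handled elsewhere).

    For the default simultaneous model with equal volumes ``ΔV`` the update is
    the exact solution of the well-mixed ODE over the burst:

    ``c ← in + (c − in) e^{−ΔV/V}``, ``x ← 1 − (1 − x) e^{−ΔV/V}``,

    volume unchanged.  With unequal volumes the analogous closed form for a
    linearly changing volume is used and the volume updates by the difference.
    The sequential model withdraws ``ΔV_out`` first, then adds ``ΔV_in``.

    Raises
    ------
    PotEmptiedError
        If the withdrawal (or the burst trajectory) empties the pot.
    """
    a = event.inflow_volume  # added, µl
    b = event.outflow_volume  # removed, µl
    v0 = state.volume
    if a == 0.0 and b == 0.0:
        return state
    inflow = event.inflow_solution

    if event_model == "sequential":
        if b >= v0 and b > 0:
            raise PotEmptiedError(
                f"withdrawal of {b} µl empties the {v0} µl pot at t = {event.time} min"
            )
        v1 = v0 - b + a
        keep = (v0 - b) / v1  # share of post-withdrawal fluid in the final mix
        comps = _combine(state.composition, inflow, keep, a / v1)
        x1 = 1.0 - (1.0 - state.x) * keep
    elif event_model == "simultaneous":
        v1 = v0 + a - b
        if v1 <= 0:
            raise PotEmptiedError(
                f"burst of −{b}/+{a} µl empties the {v0} µl pot at t = {event.time} min"
            )
        if math.isclose(a, b, rel_tol=0.0, abs_tol=1e-12):
            # constant-volume burst: exact exponential update
            v1 = v0
            decay_c = decay_old = math.exp(-a / v0) if a > 0 else 1.0
        else:
            # V(τ) varies linearly from v0 to v1 during the burst; deviations
            # of solutes from the inflow decay as (V1/V0)^(−a/(a−b)) and the
            # pump-untouched fluid mass as (V1/V0)^(−b/(a−b)).
            ratio = v1 / v0
            decay_c = ratio ** (-a / (a - b))
            decay_old = ratio ** (-b / (a - b)) * (v0 / v1)
        comps = _combine(state.composition, inflow, decay_c, 1.0 - decay_c)
        x1 = 1.0 - (1.0 - state.x) * decay_old
    else:  # pragma: no cover - guarded by type
        raise ValueError(f"unknown event model {event_model!r}")

    return replace(
        state,
        volume=v1,
        composition=Solution(comps, label=state.composition.label),
        x=min(1.0, max(0.0, x1)),
        time=max(state.time, event.time),
    )


def _combine(
    current: Solution, inflow: Solution, w_cur: float, w_in: float
) -> tuple[Component, ...]:
    """Per-component affine combine ``w_cur·current + w_in·inflow`` with unit checks."""
    from .solutions import _merged_units

    units = _merged_units((current, inflow))
    out = []
    for name, unit in units.items():
        conc = w_cur * current[name] + w_in * inflow[name]
        src = current.component(name) or inflow.component(name)
        out.append(Component(name, max(0.0, conc), unit, src.density_contribution))
    return tuple(out)


# ---------------------------------------------------------------------------
# continuous flow


def simulate_continuous(
    state: PotState,
    inflow_rate: float,
    inflow: Solution,
    duration: float,
    sample_dt: float,
    outflow_rate: float | None = None,
) -> SimTrace:
    """Integrate continuous simultaneous in/out flow with evaporation.

    Solves, with a fixed-step classical Runge–Kutta scheme (step ≤
    min(sample_dt, 0.1 min)),

    ``dV/dt = Q_in − Q_out − E/60``
    ``d(V·c_i)/dt = Q_in·inflow[c_i] − Q_out·c_i``

    where evaporation removes solvent only.  The pump-untouched fluid volume
    is integrated alongside so the trace's ``x`` series matches the event
    bookkeeping (outflow removes it proportionally; evaporation shrinks it in
    proportion to its share, leaving ``x`` unchanged at zero flow).  Matches
    the event-update closed forms to ~1e−13 on the analytic cases.

    Parameters
    ----------
    inflow_rate, outflow_rate : float
        µl/min; ``outflow_rate`` defaults to ``inflow_rate`` (constant volume
        apart from evaporation).
    duration, sample_dt : float
        Minutes; the trace is sampled every ``sample_dt`` plus the endpoint.
    """
    if inflow_rate < 0:
        raise ValueError("inflow rate must be >= 0 µl/min")
    q_in = inflow_rate
    q_out = inflow_rate if outflow_rate is None else outflow_rate
    if q_out < 0:
        raise ValueError("outflow rate must be >= 0 µl/min")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0 min")
    if duration < 0:
        raise ValueError("duration must be >= 0 min")

    from .solutions import _merged_units

    units = _merged_units((state.composition, inflow))
    names = list(units)
    e_rate = state.evaporation_rate / 60.0  # µl/min
    c_in = np.array([inflow[n] for n in names])

    # y = [V, m_1..m_k (solute masses), m_old (pump-untouched fluid volume)]
    y0 = np.concatenate(
        (
            [state.volume],
            [state.composition[n] * state.volume for n in names],
            [(1.0 - state.x) * state.volume],
        )
    )

    def rhs(y: np.ndarray) -> np.ndarray:
        v = y[0]
        if v <= 0:
            raise PotEmptiedError("pot volume reached zero during continuous flow")
        dv = q_in - q_out - e_rate
        dm = q_in * c_in - q_out * (y[1:-1] / v)
        # pump-untouched fluid is removed by outflow in proportion to its share;
        # evaporation removes solvent from old and new fluid alike, so it also
        # shrinks m_old proportionally, leaving x = 1 - m_old/V unchanged.
        dm_old = -(q_out + e_rate) * (y[-1] / v)
        return np.concatenate(([dv], dm, [dm_old]))

    sample_times = np.unique(
        np.concatenate((np.arange(0.0, duration, sample_dt), [duration]))
    )
    n_samples = len(sample_times)
    vols = np.empty(n_samples)
    xs = np.empty(n_samples)
    concs = {name: np.empty(n_samples) for name in names}

    y = y0.copy()
    t = 0.0
    for i, ts in enumerate(sample_times):
        span = ts - t
        if span > 0:
            nstep = max(1, math.ceil(span / min(sample_dt, MAX_ODE_STEP_MIN)))
            h = span / nstep
            for _ in range(nstep):
                k1 = rhs(y)
                k2 = rhs(y + 0.5 * h * k1)
                k3 = rhs(y + 0.5 * h * k2)
                k4 = rhs(y + h * k3)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t = ts
        v = y[0]
        if v <= 0:
            raise PotEmptiedError(
                f"pot volume reached zero at t = {t:.2f} min during continuous flow"
            )
        vols[i] = v
        xs[i] = min(1.0, max(0.0, 1.0 - y[-1] / v))
        for j, name in enumerate(names):
            concs[name][i] = max(0.0, y[1 + j] / v)

    return SimTrace(
        times=sample_times + state.time,
        volumes=vols,
        x=xs,
        concentrations={(n, units[n]): concs[n] for n in names},
    )


# ---------------------------------------------------------------------------
# schedule execution


def execute_schedule(
    state: PotState,
    schedule,
    sample_dt: float,
    event_model: EventModel = "simultaneous",
) -> SimTrace:
    """Run a discrete schedule: events via :func:`apply_event`, evaporation between.

    Samples are taken on a uniform ``sample_dt`` grid plus every event time
    (post-event state).  ``schedule`` is anything with an ``events`` sequence
    of :class:`ExchangeEvent`, e.g. :class:`gradpot.planner.Schedule`.

    The trace ends at the later of the last event and the schedule's declared
    duration (when it carries a provenance spec).
    """
    if sample_dt <= 0:
        raise ValueError("sample_dt must be > 0 min")
    events: Sequence[ExchangeEvent] = tuple(getattr(schedule, "events", schedule))
    if any(e2.time < e1.time for e1, e2 in zip(events, events[1:])):
        raise ValueError("schedule events must be time-ordered")

    t_end = events[-1].time if events else 0.0
    prov = getattr(schedule, "provenance", None)
    if prov is not None:
        t_end = max(t_end, prov.duration)

    grid = np.unique(
        np.concatenate(
            (
                np.arange(0.0, t_end, sample_dt),
                [e.time for e in events],
                [t_end],
            )
        )
    )
    event_at = {}
    for e in events:
        event_at.setdefault(e.time, []).append(e)

    # collect component keys up front so every series is fully populated
    from .solutions import _merged_units

    units = _merged_units(
        (state.composition, *(e.inflow_solution for e in events))
    )

    n = len(grid)
    vols = np.empty(n)
    xs = np.empty(n)
    concs = {name: np.empty(n) for name in units}

    cur = state
    t0 = state.time
    for i, t in enumerate(grid):
        target_t = t0 + t
        if target_t > cur.time:
            cur = evaporate(cur, target_t - cur.time)
        for e in event_at.get(t, ()):
            cur = apply_event(cur, e, event_model=event_model)
        vols[i] = cur.volume
        xs[i] = cur.x
        for name in units:
            concs[name][i] = cur.composition[name]

    return SimTrace(
        times=grid + t0,
        volumes=vols,
        x=xs,
        concentrations={(name, unit): concs[name] for name, unit in units.items()},
    )
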