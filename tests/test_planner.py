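"""Schedule synthesis: total-volume law, gradient modes, verification, exposure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradpot.planner import (
    GradientSpec,
    InfeasibleGradientError,
    UndefinedDerivativeError,
    exposure_report,
    plan,
    plan_equal_volume,
    plan_linear,
    plan_linear_fixed_quantum,
    rerun_composition,
    total_volume_required,
    verify_schedule,
)
from gradpot.reservoir import PotState, execute_schedule
from gradpot.solutions import Component, Solution

from conftest import make_spec

V_STANDARD = 40.0
F_STANDARD = 0.95
TOTAL_STANDARD = V_STANDARD * math.log(1 / (1 - F_STANDARD))  # 40·ln20 ≈ 119.83 µl


class TestPlanLinear:
    def test_zero_fraction_yields_empty_schedule(self, start_solution, target_solution, pot40):
        spec = make_spec(start_solution, target_solution, pot40, f=0.0)
        sched = plan_linear(spec)
        assert len(sched) == 0
        assert sched.total_inflow == 0.0

    @pytest.mark.parametrize("n", [1, 7, 40, 500])
    def test_total_volume_law_any_tick_count(self, start_solution, target_solution, pot40, n):
        spec = make_spec(start_solution, target_solution, pot40, ticks=n)
        sched = plan_linear(spec)
        assert sched.total_inflow == pytest.approx(TOTAL_STANDARD, abs=1e-9)
        assert TOTAL_STANDARD == pytest.approx(119.8293, abs=1e-4)

    def test_first_event_volume_n100(self, start_solution, target_solution, pot40):
        """First event must push x to f/n = 0.0095: ΔV = −V·ln(1 − 0.0095)."""
        spec = make_spec(start_solution, target_solution, pot40, ticks=100)
        sched = plan_linear(spec)
        oracle = -V_STANDARD * math.log(1.0 - 0.0095)  # solve 1 − e^{−ΔV/V} = 0.0095
        assert sched.ideal_volumes[0] == pytest.approx(oracle, abs=1e-12)
        assert sched.ideal_volumes[0] == pytest.approx(0.3818, abs=5e-4)

    def test_event_volumes_strictly_increase(self, lysozyme_spec):
        vols = plan_linear(lysozyme_spec).ideal_volumes
        assert all(b > a for a, b in zip(vols, vols[1:]))

    def test_total_matches_numerical_quadrature_of_flow_profile(
        self, start_solution, target_solution, pot40
    ):
        """Oracle: integrate Q(t) = V·(f/T)/(1 − f·t/T) over [0, T]."""
        spec = make_spec(start_solution, target_solution, pot40)
        f, big_t, v = spec.final_fraction, spec.duration, V_STANDARD
        t = np.linspace(0, big_t, 2_000_001)
        q = v * (f / big_t) / (1.0 - f * t / big_t)
        assert np.trapezoid(q, t) == pytest.approx(plan_linear(spec).total_inflow, rel=1e-6)

    def test_simulated_trajectory_hits_requested_ticks(self, lysozyme_spec):
        report = verify_schedule(plan_linear(lysozyme_spec), lysozyme_spec, tol=1e-9)
        assert report.passed
        assert report.max_x_deviation <= 1e-9

    def test_first_event_at_t_over_n_not_zero(self, lysozyme_spec):
        sched = plan_linear(lysozyme_spec)
        assert sched.events[0].time == pytest.approx(40.0 / 40)


class TestPlanEqualVolume:
    def test_single_tick_collapses_to_total_volume_law(
        self, start_solution, target_solution, pot40
    ):
        spec = make_spec(start_solution, target_solution, pot40, mode="equal_volume", ticks=1)
        sched = plan_equal_volume(spec)
        assert len(sched) == 1
        assert sched.ideal_volumes[0] == pytest.approx(TOTAL_STANDARD, abs=1e-9)

    def test_per_event_volume_and_midpoint_fraction(
        self, start_solution, target_solution, pot40
    ):
        spec = make_spec(start_solution, target_solution, pot40, mode="equal_volume", ticks=10)
        sched = plan_equal_volume(spec)
        assert sched.ideal_volumes[0] == pytest.approx(11.983, abs=1e-3)
        tr = execute_schedule(pot40, sched, sample_dt=spec.duration)
        t5 = spec.duration * 5 / 10
        idx = np.argmin(np.abs(tr.times - t5))
        # after 5 of 10 events: x = 1 − e^{−5·v/V} = 1 − (1−f)^{1/2}
        assert tr.x[idx] == pytest.approx(1.0 - math.sqrt(0.05), abs=1e-9)
        assert tr.x[idx] == pytest.approx(0.7764, abs=1e-4)

    def test_volumes_constant_and_totals_match_linear(self, start_solution,
                                                      target_solution, pot40):
        spec = make_spec(start_solution, target_solution, pot40, mode="equal_volume", ticks=33)
        sched = plan_equal_volume(spec)
        assert len(set(sched.ideal_volumes)) == 1
        lin = plan_linear(make_spec(start_solution, target_solution, pot40, ticks=33))
        assert sched.total_inflow == pytest.approx(lin.total_inflow, abs=1e-9)

    def test_exponential_shaped_trajectory(self, start_solution, target_solution, pot40):
        spec = make_spec(start_solution, target_solution, pot40, mode="equal_volume", ticks=20)
        report = verify_schedule(plan_equal_volume(spec), spec, tol=1e-9)
        assert report.passed


class TestLinearFixedQuantum:
    def test_constant_volumes_at_warped_times(self, start_solution, target_solution, pot40):
        spec = make_spec(
            start_solution, target_solution, pot40, mode="linear_fixed_quantum", ticks=25
        )
        sched = plan_linear_fixed_quantum(spec)
        assert len(set(sched.ideal_volumes)) == 1
        assert sched.total_inflow == pytest.approx(TOTAL_STANDARD, abs=1e-9)
        # event k fires exactly when the linear ramp calls for its x value
        report = verify_schedule(sched, spec, tol=1e-9)
        assert report.passed
        t, x = spec.requested_trajectory()
        np.testing.assert_allclose(x, spec.final_fraction * t / spec.duration, atol=1e-12)


class TestSpecValidation:
    def test_fraction_one_is_infeasible(self, start_solution, target_solution, pot40):
        with pytest.raises(InfeasibleGradientError):
            make_spec(start_solution, target_solution, pot40, f=1.0)
        with pytest.raises(InfeasibleGradientError):
            total_volume_required(40.0, 1.0)

    @pytest.mark.parametrize("kw", [{"duration": 0.0}, {"ticks": 0}])
    def test_nonpositive_duration_or_ticks_rejected(
        self, start_solution, target_solution, pot40, kw
    ):
        with pytest.raises(ValueError):
            make_spec(start_solution, target_solution, pot40, **kw)


class TestRerunComposition:
    def test_identity_with_zero_second_run(self):
        assert rerun_composition(0.77, 0.0) == pytest.approx(0.77)

    @pytest.mark.parametrize("f,expected", [(0.95, 0.9975), (0.98, 0.9996)])
    def test_double_execution_fractions(self, f, expected):
        assert rerun_composition(f, f) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_back_to_back_simulation(
        self, start_solution, target_solution, pot40
    ):
        spec = make_spec(start_solution, target_solution, pot40, ticks=20)
        sched = plan(spec)
        tr1 = execute_schedule(pot40, sched, sample_dt=spec.duration)
        state1 = tr1.final_state()
        tr2 = execute_schedule(state1, sched, sample_dt=spec.duration)
        assert tr2.x[-1] == pytest.approx(rerun_composition(0.95, 0.95), abs=1e-9)

    def test_rejects_fraction_one(self):
        with pytest.raises(InfeasibleGradientError):
            rerun_composition(1.0, 0.5)


class TestVerifySchedule:
    def test_evaporation_causes_reported_deviation(
        self, start_solution, target_solution
    ):
        pot = PotState(
            volume=40.0, composition=start_solution, evaporation_rate=6.0
        )
        spec = make_spec(start_solution, target_solution, pot, duration=180.0, ticks=60)
        report = verify_schedule(plan(spec), spec, tol=1e-9)
        assert not report.passed
        assert report.max_x_deviation > 1e-6

    def test_half_volume_schedule_fails_with_sqrt_shortfall(
        self, start_solution, target_solution, pot40, lysozyme_spec
    ):
        from dataclasses import replace
        from gradpot.planner import Schedule

        full = plan(lysozyme_spec)
        halved = Schedule(
            tuple(
                replace(e, inflow_volume=e.inflow_volume / 2, outflow_volume=e.outflow_volume / 2)
                for e in full.events
            ),
            tuple(v / 2 for v in full.ideal_volumes),
            provenance=full.provenance,
        )
        report = verify_schedule(halved, lysozyme_spec, tol=1e-9)
        assert not report.passed
        expected_final = 1.0 - math.sqrt(1.0 - 0.95)
        assert report.final_x == pytest.approx(expected_final, abs=1e-9)

    def test_tolerance_must_be_positive(self, lysozyme_spec):
        with pytest.raises(ValueError):
            verify_schedule(plan(lysozyme_spec), lysozyme_spec, tol=0.0)


class TestExposureReport:
    def test_constant_trace_has_zero_rates(self, pot40):
        tr = execute_schedule(pot40, (), sample_dt=1.0)
        # a single-sample trace cannot define a rate
        if len(tr) < 2:
            with pytest.raises(UndefinedDerivativeError):
                exposure_report(tr)
        else:
            m = exposure_report(tr)
            assert m.max_dx_dt == 0.0

    def test_single_sample_raises(self, pot40):
        from gradpot.reservoir import SimTrace

        tr = SimTrace(
            times=np.array([0.0]), volumes=np.array([40.0]),
            x=np.array([0.0]), concentrations={},
        )
        with pytest.raises(UndefinedDerivativeError):
            exposure_report(tr)

    def test_linear_mode_rate_is_f_over_t_at_tick_sampling(self, lysozyme_spec):
        sched = plan(lysozyme_spec)
        tick = lysozyme_spec.duration / lysozyme_spec.ticks
        tr = execute_schedule(lysozyme_spec.pot, sched, sample_dt=tick)
        m = exposure_report(tr, lysozyme_spec.final_fraction)
        assert m.max_dx_dt == pytest.approx(0.95 / 40.0, rel=1e-9)
        assert m.t_half == pytest.approx(20.0, abs=tick)
        assert m.t_95 == pytest.approx(38.0, abs=tick)

    def test_equal_volume_mode_steepest_at_first_event(
        self, start_solution, target_solution, pot40
    ):
        n, big_t, f = 10, 40.0, 0.95
        spec = make_spec(start_solution, target_solution, pot40,
                         mode="equal_volume", ticks=n, duration=big_t)
        tr = execute_schedule(pot40, plan(spec), sample_dt=big_t / n)
        m = exposure_report(tr, f)
        first_step = 1.0 - (1.0 - f) ** (1.0 / n)
        assert m.max_dx_dt == pytest.approx(first_step / (big_t / n), rel=1e-9)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    v=st.floats(10.0, 100.0),
    f=st.floats(0.5, 0.99),
    n=st.integers(1, 500),
    mode=st.sampled_from(["linear", "equal_volume"]),
)
def test_planner_simulator_agreement(v, f, n, mode):
    """With no evaporation, the simulated x hits the requested trajectory to 1e-9."""
    start = Solution((Component("NaCl", 8.0, "%w/v"),))
    target = Solution((Component("NaCl", 3.0, "%w/v"),))
    pot = PotState(volume=v, composition=start)
    spec = GradientSpec(start=start, target=target, final_fraction=f,
                        duration=30.0, mode=mode, ticks=n, pot=pot)
    sched = plan(spec)
    assert sched.total_inflow == pytest.approx(v * math.log(1 / (1 - f)), abs=1e-9)
    report = verify_schedule(sched, spec, tol=1e-9)
    assert report.passed, report
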