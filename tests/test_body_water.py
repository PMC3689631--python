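"""Dosing schedules, enrichment simulation and time-averaged precursor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from epiturn.body_water import (
    BodyWaterParams,
    DoseEvent,
    DosingSchedule,
    EnrichmentCurve,
    build_protocol_schedule,
    interpolate_measured,
    simulate_body_water,
    time_averaged_enrichment,
)
from epiturn.errors import DomainError, InsufficientDataError, InvalidInputError


class TestProtocolSchedule:
    def test_16_days_weekdays_twice_daily(self):
        # 16 consecutive days starting Monday contain 12 weekdays
        sched = build_protocol_schedule(16)
        assert len(sched) == 24

    def test_38_days_weekdays_twice_daily(self):
        # 38 consecutive days starting Monday contain 28 weekdays
        sched = build_protocol_schedule(38)
        assert len(sched) == 56

    def test_single_day_once_daily_all_days(self):
        sched = build_protocol_schedule(1, doses_per_day=1, weekday_pattern=range(7))
        assert len(sched) == 1

    def test_empty_pattern_rejected(self):
        with pytest.raises(InvalidInputError):
            build_protocol_schedule(16, weekday_pattern=())

    def test_weekend_gap_in_event_times(self):
        days = np.floor(build_protocol_schedule(14).days).astype(int)
        assert set(days) == {0, 1, 2, 3, 4, 7, 8, 9, 10, 11}


class TestSimulation:
    def test_empty_schedule_is_zero(self):
        curve = simulate_body_water(DosingSchedule(()), BodyWaterParams())
        assert np.all(curve.values == 0)

    def test_single_dose_no_turnover(self):
        # 50 mL x 70% into 35 L with zero turnover: flat 0.1% after the dose
        sched = DosingSchedule((DoseEvent(0.5, 50.0, 0.70),))
        params = BodyWaterParams(volume_l=35.0, turnover_per_day=0.0)
        curve = simulate_body_water(sched, params, grid=np.linspace(0, 5, 101))
        assert curve.value_at(0.4) == 0.0
        assert curve.value_at(3.0) == pytest.approx(0.001, abs=1e-15)

    def test_matches_ode_integration_oracle(self):
        """Closed-form superposition vs numerical ODE with impulse doses."""
        sched = build_protocol_schedule(14)
        params = BodyWaterParams()
        grid = np.arange(0.0, 16.0, 0.05)
        curve = simulate_body_water(sched, params, grid)

        deltas = {e.day: e.volume_ml * e.purity / (params.volume_l * 1000) for e in sched.events}
        dose_days = sorted(deltas)
        p, t_prev, out = 0.0, 0.0, []
        checkpoints = sorted(set(dose_days) | set(grid))
        values = {}
        for t in checkpoints:
            if t > t_prev:
                sol = solve_ivp(
                    lambda _, y: [-params.turnover_per_day * y[0]],
                    (t_prev, t), [p], rtol=1e-11, atol=1e-14,
                )
                p = sol.y[0, -1]
            t_prev = t
            values[t] = p
            if t in deltas:
                p += deltas[t]
        oracle = np.array([values[t] for t in grid])
        np.testing.assert_allclose(curve.values, oracle, atol=1e-8)

    def test_rise_to_plateau_with_weekend_dips(self):
        sched = build_protocol_schedule(28)
        curve = simulate_body_water(sched, BodyWaterParams())
        # second week runs higher than first; weekend (days 5-7) dips
        assert curve.value_at(12.0) > curve.value_at(5.0)
        assert curve.value_at(7.2) < curve.value_at(5.2)

    def test_plateau_bounded_by_continuous_limit(self):
        params = BodyWaterParams()
        sched = build_protocol_schedule(60)
        curve = simulate_body_water(sched, params)
        bound = (2 * 50.0 * 0.70) / (params.volume_l * 1000 * params.turnover_per_day)
        assert curve.values.max() <= bound

    def test_superposition_linearity(self):
        full = build_protocol_schedule(21)
        a = DosingSchedule(full.events[::2])
        b = DosingSchedule(full.events[1::2])
        grid = np.arange(0.0, 23.0, 0.1)
        params = BodyWaterParams()
        total = simulate_body_water(full, params, grid).values
        parts = (simulate_body_water(a, params, grid).values
                 + simulate_body_water(b, params, grid).values)
        np.testing.assert_allclose(total, parts, atol=1e-12)


class TestMeasuredCurve:
    def test_linear_midpoint(self):
        curve = interpolate_measured([(0, 0.0), (10, 0.02)])
        assert curve.value_at(5.0) == pytest.approx(0.01)

    def test_prepends_zero_origin(self):
        curve = interpolate_measured([(3, 0.01), (10, 0.02)])
        assert curve.value_at(0.0) == 0.0
        assert curve.provenance == "measured-interpolated"

    def test_constant_points_give_constant_curve(self):
        curve = interpolate_measured([(0, 0.015), (5, 0.015), (9, 0.015)])
        assert np.all(curve.value_at(np.linspace(0, 12, 30)) == 0.015)

    def test_duplicate_days_rejected(self):
        with pytest.raises(InvalidInputError):
            interpolate_measured([(3, 0.01), (3, 0.02), (5, 0.01)])

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            interpolate_measured([(3, 0.01)])


class TestTimeAveragedEnrichment:
    def test_constant_curve(self):
        curve = EnrichmentCurve(np.array([0.0, 20.0]), np.array([0.015, 0.015]))
        assert time_averaged_enrichment(curve, 7.3) == pytest.approx(0.015)

    def test_linear_ramp_triangle_area(self):
        curve = EnrichmentCurve(np.array([0.0, 10.0]), np.array([0.0, 0.02]))
        assert time_averaged_enrichment(curve, 10.0) == pytest.approx(0.01)

    def test_nonpositive_time_rejected(self):
        curve = EnrichmentCurve(np.array([0.0, 10.0]), np.array([0.0, 0.02]))
        with pytest.raises(DomainError):
            time_averaged_enrichment(curve, 0.0)

    def test_sawtooth_matches_quadrature_oracle(self):
        """Independent fine-grid quadrature of the curve's interpolant,
        including an off-grid endpoint."""
        sched = build_protocol_schedule(21)
        curve = simulate_body_water(sched, BodyWaterParams())
        t = 16.97  # off the native 0.05-day grid
        refined = np.union1d(np.linspace(0.0, t, 5001), curve.days[curve.days < t])
        integral = np.trapezoid(curve.value_at(refined), refined)
        assert time_averaged_enrichment(curve, t) == pytest.approx(integral / t, rel=1e-6)

    def test_extrapolation_warns(self):
        curve = EnrichmentCurve(np.array([0.0, 10.0]), np.array([0.0, 0.02]))
        with pytest.warns(UserWarning, match="extrapolat"):
            time_averaged_enrichment(curve, 15.0)

    @given(t=st.floats(0.5, 20.0))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_average_bounded_by_curve_extremes(self, t):
        sched = build_protocol_schedule(21)
        curve = simulate_body_water(sched, BodyWaterParams())
        avg = time_averaged_enrichment(curve, t)
        window = curve.values[curve.days <= t + 1e-12]
        assert window.min() - 1e-12 <= avg <= window.max() + 1e-12
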