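"""PI controller: output arithmetic, saturation and anti-windup, set-point
schedules, dual-feature control, and closed-loop behaviour on the plant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respclamp.control import (
    ControllerConfig,
    ControllerState,
    ScheduleError,
    SetpointSchedule,
    control_error,
    dual_control_step,
    pi_output,
    setpoint_value,
)
from respclamp.experiments import closed_loop_session, HOUR


class TestErrorSignal:
    @pytest.mark.parametrize(
        "p_star,p_tau,expected", [(0.5, 0.5, 0.0), (0.7, 0.5, 0.2), (0.3, 0.5, -0.2)]
    )
    def test_error_is_setpoint_minus_estimate(self, p_star, p_tau, expected):
        assert control_error(p_star, p_tau) == pytest.approx(expected)


class TestPIOutput:
    def test_first_step_arithmetic(self):
        # A = 300 + 400*0.1 + 80*0.1 = 348 mV
        cfg = ControllerConfig(a_baseline=300.0)
        amp, state = pi_output(cfg, ControllerState(), 0.1)
        assert amp == pytest.approx(348.0)
        assert state.integral_sum == pytest.approx(0.1)

    def test_zero_error_returns_baseline(self):
        cfg = ControllerConfig(a_baseline=300.0)
        amp, _ = pi_output(cfg, ControllerState(), 0.0)
        assert amp == pytest.approx(300.0)

    def test_output_clamped_to_stimulator_ceiling(self):
        cfg = ControllerConfig(a_baseline=1000.0)
        amp, _ = pi_output(cfg, ControllerState(), 0.25)
        assert amp == 1000.0

    def test_antiwindup_freezes_integral_at_saturation(self):
        cfg = ControllerConfig(a_baseline=990.0)
        state = ControllerState()
        for _ in range(50):
            amp, state = pi_output(cfg, state, 0.5)
        assert amp == 1000.0
        assert state.integral_sum <= 0.5  # did not accumulate 50 * 0.5

    def test_integral_disabled_in_p_only_mode(self):
        cfg = ControllerConfig(a_baseline=300.0, integral_enabled=False)
        state = ControllerState()
        for _ in range(10):
            amp, state = pi_output(cfg, state, 0.1)
        assert state.integral_sum == 0.0
        assert amp == pytest.approx(300.0 + 400.0 * 0.1)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=100))
    def test_output_always_within_actuator_range(self, errors):
        cfg = ControllerConfig(a_baseline=350.0)
        state = ControllerState()
        for e in errors:
            amp, state = pi_output(cfg, state, e)
            assert 100.0 <= amp <= 1000.0


class TestSetpointSchedule:
    def test_sine_at_zero_and_quarter_period(self):
        sched = SetpointSchedule(kind="sine", base=0.5, sine_amplitude=0.2,
                                 sine_period=3600.0)
        assert setpoint_value(sched, 0.0) == pytest.approx(0.5)
        assert setpoint_value(sched, 900.0) == pytest.approx(0.7)

    def test_piecewise_segment_lookup(self):
        sched = SetpointSchedule(
            kind="piecewise", segments=((0.0, 0.3), (7200.0, 0.7))
        )
        assert setpoint_value(sched, 8000.0) == 0.7
        assert setpoint_value(sched, 100.0) == 0.3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "constant", "base": 0.0},
            {"kind": "sine", "base": 0.9, "sine_amplitude": 0.2},
            {"kind": "piecewise", "segments": ((0.0, 1.5),)},
        ],
    )
    def test_values_outside_unit_interval_rejected(self, kwargs):
        with pytest.raises(ScheduleError):
            SetpointSchedule(**kwargs)


class TestDualControl:
    def test_latency_inside_band_reduces_to_probability_control(self):
        cfg = ControllerConfig(a_baseline=300.0)
        a1, _ = dual_control_step(cfg, ControllerState(), 0.1, l_tau=45.0)
        a2, _ = pi_output(cfg, ControllerState(), 0.1)
        assert a1 == a2

    def test_long_latency_raises_amplitude(self):
        cfg = ControllerConfig(a_baseline=300.0)
        a_dual, _ = dual_control_step(cfg, ControllerState(), 0.1, l_tau=150.0)
        a_prob, _ = pi_output(cfg, ControllerState(), 0.1)
        assert a_dual > a_prob

    def test_zero_weight_degenerates_to_pi(self):
        cfg = ControllerConfig(a_baseline=300.0, latency_weight=0.0)
        a_dual, _ = dual_control_step(cfg, ControllerState(), 0.2, l_tau=300.0)
        a_prob, _ = pi_output(cfg, ControllerState(), 0.2)
        assert a_dual == a_prob

    def test_missing_estimate_contributes_no_error(self):
        cfg = ControllerConfig(a_baseline=300.0)
        a_dual, _ = dual_control_step(cfg, ControllerState(), 0.1, l_tau=None)
        a_prob, _ = pi_output(cfg, ControllerState(), 0.1)
        assert a_dual == a_prob


class TestClosedLoopOnPlant:
    @pytest.mark.parametrize("p_star", [0.3, 0.5, 0.7])
    def test_static_plant_converges_to_setpoint(self, p_star):
        log, _ = closed_loop_session(
            p_star, 3 * HOUR, seed=101, drift=False, plasticity=False,
            record_electrodes=False,
        )
        final = log.trials[log.trials.t_n_s >= log.start_time + 2 * HOUR]
        assert abs(final.p_tau.mean() - p_star) < 0.05

    def test_p_only_mode_has_larger_offset_than_pi(self):
        # same drifting plant seed; the integral removes the steady-state error
        offsets = {}
        for integral in (True, False):
            log, _ = closed_loop_session(
                0.5, 2 * HOUR, seed=55, integral_enabled=integral,
                record_electrodes=False,
            )
            post = log.post_transient(500.0)
            offsets[integral] = abs(post.p_tau.mean() - 0.5)
        assert offsets[False] >= offsets[True]

    def test_higher_setpoint_needs_higher_amplitude(self):
        means = []
        for p_star in (0.3, 0.5, 0.7):
            log, _ = closed_loop_session(
                p_star, HOUR, seed=77, record_electrodes=False
            )
            means.append(log.post_transient(500.0).amplitude_mV.mean())
        assert means[0] < means[1] < means[2]
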