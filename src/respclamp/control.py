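"""PI response clamp: error signal, bounded PI output, set-point schedules,
and simultaneous probability-plus-latency control.

The controller maps the probability error e(n) = P*(n) - P_tau(n) to the next
stimulation amplitude

    A(n) = A_baseline + g_P * e(n) + g_I * sum_i e(i)

with gains in mV per unit probability error (defaults 400 and 80 mV — a
normalized proportional gain of 1 and integral gain of 0.2 on a 400 mV scale),
clamped to the stimulator's electrochemically safe 100-1000 mV range.  The
integral is conditionally frozen while the actuator is saturated in the
direction the error is pushing (anti-windup), since an unbounded sum against a
bounded actuator would otherwise wind up during unresponsive episodes.

Dual-feature control folds a latency error into the same loop: when the latency
estimate sits outside its commanded band, the (band-normalized) excess is added
to the probability error.  Raising amplitude both raises response probability
and shortens latency, so a single actuator can serve both errors to the extent
their demands are compatible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "SetpointSchedule",
    "ControllerConfig",
    "ControllerState",
    "ScheduleError",
    "control_error",
    "pi_output",
    "setpoint_value",
    "dual_control_step",
    "latency_error",
]


class ScheduleError(ValueError):
    """Set-point schedule outside the open interval (0, 1)."""


@dataclass(frozen=True)
class SetpointSchedule:
    """P*(t): constant, sine, or piecewise-constant schedule.

    sine: base + sine_amplitude * sin(2*pi*t / sine_period).
    piecewise: ``segments`` is a list of (t_start_s, value); the active segment
    is the last one whose start is <= t.
    """

    kind: str = "constant"
    base: float = 0.5
    sine_amplitude: float = 0.2
    sine_period: float = 3600.0
    segments: tuple = ()

    def __post_init__(self):
        if self.kind not in ("constant", "sine", "piecewise"):
            raise ScheduleError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "constant" and not 0.0 < self.base < 1.0:
            raise ScheduleError("constant set-point must be in (0, 1)")
        if self.kind == "sine":
            for extreme in (self.base - self.sine_amplitude,
                            self.base + self.sine_amplitude):
                if not 0.0 < extreme < 1.0:
                    raise ScheduleError("sine schedule leaves (0, 1)")
            if self.sine_period <= 0:
                raise ScheduleError("sine_period must be > 0")
        if self.kind == "piecewise":
            if not self.segments:
                raise ScheduleError("piecewise schedule needs segments")
            for t0, v in self.segments:
                if not 0.0 < v < 1.0:
                    raise ScheduleError("piecewise values must be in (0, 1)")

    @classmethod
    def constant(cls, p_star: float) -> "SetpointSchedule":
        return cls(kind="constant", base=p_star)


def setpoint_value(schedule: SetpointSchedule, t: float) -> float:
    """Evaluate P*(t)."""
    if schedule.kind == "constant":
        return schedule.base
    if schedule.kind == "sine":
        return schedule.base + schedule.sine_amplitude * math.sin(
            2.0 * math.pi * t / schedule.sine_period
        )
    active = schedule.segments[0][1]
    for t0, v in schedule.segments:
        if t >= t0:
            active = v
    return active


@dataclass
class ControllerConfig:
    setpoint: SetpointSchedule = field(
        default_factory=lambda: SetpointSchedule.constant(0.5)
    )
    g_p: float = 400.0             # mV per unit probability error
    g_i: float = 80.0              # mV per unit accumulated error
    a_baseline: float = 350.0      # mV
    a_min: float = 100.0           # mV
    a_max: float = 1000.0          # mV
    integral_enabled: bool = True  # False = P-only mode
    latency_weight: float = 1.0    # weight of the latency error in dual control
    latency_band: tuple[float, float] = (10.0, 80.0)  # ms

    def __post_init__(self):
        if not self.a_min < self.a_max:
            raise ValueError("a_min must be below a_max")
        if self.g_p < 0 or self.g_i < 0:
            raise ValueError("gains must be >= 0")


@dataclass(frozen=True)
class ControllerState:
    integral_sum: float = 0.0
    last_error: float = 0.0
    last_output: float = 350.0     # mV


def control_error(p_star_t: float, p_tau: float) -> float:
    """Error signal e(n) = P*(n) - P_tau(n)."""
    return p_star_t - p_tau


def pi_output(
    cfg: ControllerConfig, state: ControllerState, e: float
) -> tuple[float, ControllerState]:
    """Next stimulation amplitude from the current error; clamped with anti-windup.

    The integral increment is discarded when the raw output is saturated and the
    error drives further into the same bound (conditional integration).
    """
    if not math.isfinite(e):
        raise ValueError("error must be finite")
    integral = state.integral_sum + e if cfg.integral_enabled else 0.0
    raw = cfg.a_baseline + cfg.g_p * e + cfg.g_i * integral
    if cfg.integral_enabled and (
        (raw > cfg.a_max and e > 0) or (raw < cfg.a_min and e < 0)
    ):
        integral = state.integral_sum  # freeze: actuator cannot follow
        raw = cfg.a_baseline + cfg.g_p * e + cfg.g_i * integral
    out = min(max(raw, cfg.a_min), cfg.a_max)
    return out, ControllerState(
        integral_sum=integral, last_error=e, last_output=out
    )


def latency_error(cfg: ControllerConfig, l_tau: Optional[float]) -> float:
    """Band-normalized latency error: 0 inside the band or with no estimate.

    Outside the band the error is the band-width-normalized excess beyond the
    nearest edge, positive when latency is too long — which raises amplitude
    and shortens latency.  Referencing the edge (a dead-zone error) keeps the
    combined error continuous; an error that jumped to a finite value at the
    edge would hit the plant with a discontinuous proportional kick every time
    the estimate crossed the band boundary.
    """
    if l_tau is None:
        return 0.0
    lo, hi = cfg.latency_band
    if l_tau > hi:
        return (l_tau - hi) / (hi - lo)
    if l_tau < lo:
        return (l_tau - lo) / (hi - lo)
    return 0.0


def dual_control_step(
    cfg: ControllerConfig,
    state: ControllerState,
    e_prob: float,
    l_tau: Optional[float],
) -> tuple[float, ControllerState]:
    """PI step on the combined error e_prob + latency_weight * e_lat."""
    e = e_prob + cfg.latency_weight * latency_error(cfg, l_tau)
    return pi_output(cfg, state, e)
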