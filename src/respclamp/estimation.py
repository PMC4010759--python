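"""Online exponential-kernel estimators of response probability and latency.

The probability estimate after the n-th stimulus is the recursion

    P_tau(n) = (1 - exp(-dt/tau)) * y(n) + exp(-dt/tau) * P_tau(n-1)

with dt the time since the previous stimulus; tau (typically 250 s) trades
fluctuation suppression against responsiveness of the estimate.  The latency
estimate applies the same kernel over responded trials only (latency is
undefined when y = 0), weighting by real elapsed time between responses.

``estimate_from_history`` is a non-recursive kernel sum over the full history,
kept as an independent cross-check of the recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

__all__ = [
    "EstimatorState",
    "TemporalOrderError",
    "update_probability_estimate",
    "update_latency_estimate",
    "estimate_from_history",
    "latency_estimate_from_history",
]


class TemporalOrderError(ValueError):
    """Stimulus timestamps must be strictly increasing."""


@dataclass(frozen=True)
class EstimatorState:
    """Joint state of the probability and latency estimators."""

    p_tau: float                # probability estimate, in [0, 1]
    tau: float                  # s
    last_time: float            # s, time of the last probability update
    l_tau: Optional[float] = None         # ms, latency estimate
    last_response_time: Optional[float] = None  # s, last responded trial

    def __post_init__(self):
        if not 0.0 <= self.p_tau <= 1.0:
            raise ValueError("p_tau must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def update_probability_estimate(
    state: EstimatorState, y: int, t_n: float
) -> EstimatorState:
    """One step of the exponential-kernel probability recursion."""
    if t_n <= state.last_time:
        raise TemporalOrderError(
            f"t_n={t_n} not after previous update at {state.last_time}"
        )
    if y not in (0, 1):
        raise ValueError("y must be binary")
    a = math.exp(-(t_n - state.last_time) / state.tau)
    return replace(state, p_tau=(1.0 - a) * y + a * state.p_tau, last_time=t_n)


def update_latency_estimate(
    state: EstimatorState, latency: Optional[float], t_n: float
) -> EstimatorState:
    """Kernel update of the latency estimate; non-response trials are skipped.

    The first observed latency initialises the estimate.  The kernel weight
    uses the real time elapsed since the previous responded trial.
    """
    if latency is None:
        return state
    if latency < 0:
        raise ValueError("latency must be nonnegative")
    if state.l_tau is None or state.last_response_time is None:
        return replace(state, l_tau=float(latency), last_response_time=t_n)
    if t_n <= state.last_response_time:
        raise TemporalOrderError("latency updates must move forward in time")
    a = math.exp(-(t_n - state.last_response_time) / state.tau)
    return replace(
        state,
        l_tau=(1.0 - a) * latency + a * state.l_tau,
        last_response_time=t_n,
    )


def estimate_from_history(
    y_series: Sequence[int],
    times: Sequence[float],
    tau: float,
    p0: float,
    t0: float = 0.0,
) -> float:
    """Explicit (non-recursive) kernel-weighted probability estimate.

    Each observation y(i) at time t_i carries weight
    (1 - exp(-dt_i/tau)) * prod_{j>i} exp(-dt_j/tau); the initial value p0 at
    t0 carries the remaining weight.  Serves as the brute-force oracle for
    :func:`update_probability_estimate`.
    """
    if len(y_series) != len(times):
        raise ValueError("y_series and times must have equal length")
    value = 0.0
    carry = 1.0  # product of decay factors applied to everything before i
    # walk backwards so each term's forward decay product is accumulated once
    for i in range(len(times) - 1, -1, -1):
        dt = times[i] - (times[i - 1] if i > 0 else t0)
        if dt <= 0:
            raise TemporalOrderError("times must be strictly increasing")
        value += carry * (1.0 - math.exp(-dt / tau)) * y_series[i]
        carry *= math.exp(-dt / tau)
    return value + carry * p0


def latency_estimate_from_history(
    latencies: Sequence[Optional[float]],
    times: Sequence[float],
    tau: float,
) -> Optional[float]:
    """Explicit kernel average over responded trials only (oracle form)."""
    if len(latencies) != len(times):
        raise ValueError("latencies and times must have equal length")
    observed = [(t, l) for t, l in zip(times, latencies) if l is not None]
    if not observed:
        return None
    m = len(observed)
    # explicit weights: each response i > 0 contributes (1 - a_i) * prod a_j (j > i);
    # the first response carries the residual weight prod_{j>=1} a_j
    decays = [
        math.exp(-(observed[i][0] - observed[i - 1][0]) / tau) for i in range(1, m)
    ]
    value = 0.0
    for i in range(1, m):
        tail = 1.0
        for j in range(i, m - 1):
            tail *= decays[j]
        value += (1.0 - decays[i - 1]) * tail * observed[i][1]
    residual = 1.0
    for d in decays:
        residual *= d
    return value + residual * observed[0][1]
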