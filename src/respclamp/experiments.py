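"""Canonical experiment batteries over the synthetic plant.

These functions encode the study conditions used throughout the repository —
set-points, session durations, estimator time constant, stimulation rate — so
the narrative analysis scripts, the test suite and the acceptance script all
run literally the same protocols.  All randomness derives from a single seed
fanned out through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .analysis import (
    io_curves_by_epoch,
    io_stability,
    pairwise_latency_correlations,
    probability_trace_stats,
    spontaneous_evoked_rates,
)
from .control import ControllerConfig, SetpointSchedule
from .plant import Plant, PlantConfig
from .sessions import (
    SessionLog,
    calibrate_baseline,
    run_closed_loop,
    run_no_stimulation,
    run_open_loop,
    shuffled_series,
)

__all__ = [
    "child_seeds",
    "make_plant",
    "closed_loop_session",
    "quenching_battery",
    "setpoint_attainment",
    "dual_control_session",
    "dual_control_latency",
    "quench_vs_shuffle",
    "amplitude_vs_setpoint",
    "io_stability_closed_vs_open",
    "correlation_dispersion",
    "spontaneous_tradeoff",
]

STIM_PERIOD = 5.0       # s (0.2 Hz)
TAU = 250.0             # s
TRANSIENT_S = 2 * TAU   # discarded from summary statistics
HOUR = 3600.0


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic fan-out of one global seed into n child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def make_plant(
    seed: int,
    drift: bool = True,
    plasticity: bool = True,
    **overrides,
) -> Plant:
    """Default-calibration plant; drift/plasticity can be switched off."""
    cfg = PlantConfig(seed=seed, **overrides)
    if not drift:
        cfg.drift_sd = 0.0
        cfg.latency_drift_sd = 0.0
    if not plasticity:
        cfg.plasticity_rate = 0.0
        cfg.dispersion_rate = 0.0
    cfg.validate()
    return Plant(cfg)


def closed_loop_session(
    p_star: float,
    duration_s: float,
    seed: int,
    drift: bool = True,
    plasticity: bool = True,
    tau: float = TAU,
    dual_control_start: Optional[float] = None,
    integral_enabled: bool = True,
    record_electrodes: bool = True,
    plant: Optional[Plant] = None,
    **plant_overrides,
) -> tuple[SessionLog, Plant]:
    """One closed-loop clamp session with calibrated baseline amplitude."""
    if plant is None:
        plant = make_plant(seed, drift=drift, plasticity=plasticity,
                           **plant_overrides)
    baseline = calibrate_baseline(plant, p_star)
    ctrl = ControllerConfig(
        setpoint=SetpointSchedule.constant(p_star),
        a_baseline=baseline,
        integral_enabled=integral_enabled,
    )
    log = run_closed_loop(
        plant, ctrl, duration_s, stim_period=STIM_PERIOD, tau=tau,
        dual_control_start=dual_control_start,
        record_electrodes=record_electrodes,
    )
    return log, plant


def quenching_battery(
    seed: int,
    p_stars: Iterable[float] = (0.2, 0.3, 0.5, 0.7),
    seeds_per_setpoint: int = 2,
    duration_s: float = 2 * HOUR,
) -> pd.DataFrame:
    """Fluctuation quenching across set-points on the drifting plant.

    Eight 2 h closed-loop sessions by default (set-points spanning 0.2-0.7,
    two plant seeds each); reports the post-transient SD of P_tau per session.
    """
    p_stars = list(p_stars)
    seeds = child_seeds(seed, len(p_stars) * seeds_per_setpoint)
    rows = []
    i = 0
    for p_star in p_stars:
        for _ in range(seeds_per_setpoint):
            log, _ = closed_loop_session(
                p_star, duration_s, seeds[i], record_electrodes=False
            )
            mean, sd = probability_trace_stats(log, TRANSIENT_S)
            rows.append((p_star, seeds[i], mean, sd))
            i += 1
    return pd.DataFrame(rows, columns=["p_star", "seed", "mean_p_tau", "sd_p_tau"])


def setpoint_attainment(
    p_star: float,
    seed: int,
    n_seeds: int = 10,
    duration_s: float = 3 * HOUR,
    drift: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Mean P_tau over the final hour of closed-loop sessions at ``p_star``.

    Returns the across-seed average and the per-seed table.
    """
    rows = []
    for s in child_seeds(seed, n_seeds):
        log, _ = closed_loop_session(
            p_star, duration_s, s, drift=drift, record_electrodes=False
        )
        final = log.trials[log.trials.t_n_s >= log.start_time + duration_s - HOUR]
        rows.append((s, float(final.p_tau.mean())))
    df = pd.DataFrame(rows, columns=["seed", "mean_p_tau_final_hour"])
    return float(df.mean_p_tau_final_hour.mean()), df


def dual_control_session(
    seed: int,
    p_star: float = 0.3,
    phase_s: float = 2 * HOUR,
) -> SessionLog:
    """Probability-only control followed by simultaneous probability+latency
    control (band 10-80 ms), each phase ``phase_s`` long, on one plant."""
    log, _ = closed_loop_session(
        p_star, 2 * phase_s, seed, dual_control_start=phase_s,
        record_electrodes=False,
    )
    return log


def dual_control_latency(
    seed: int, n_seeds: int = 10, phase_s: float = 2 * HOUR
) -> tuple[float, pd.DataFrame]:
    """Mean evoked latency over the final hour of dual control, across seeds."""
    rows = []
    for s in child_seeds(seed, n_seeds):
        log = dual_control_session(s, phase_s=phase_s)
        t_end = log.start_time + 2 * phase_s
        final = log.trials[(log.trials.t_n_s >= t_end - HOUR) & (log.trials.y == 1)]
        rows.append((s, float(final.latency_ms.mean())))
    df = pd.DataFrame(rows, columns=["seed", "mean_latency_ms_final_hour"])
    return float(df.mean_latency_ms_final_hour.mean()), df


# --- paired direction-of-effect experiments ----------------------------------


def quench_vs_shuffle(
    seed: int, duration_s: float = 2 * HOUR, p_star: float = 0.5
) -> tuple[float, float]:
    """SD of P_tau: closed loop vs its shuffled replay on an independently
    seeded drifting plant.  Returns (sd_closed, sd_shuffled)."""
    s_closed, s_shuffle, s_plant2 = child_seeds(seed, 3)
    log, _ = closed_loop_session(
        p_star, duration_s, s_closed, record_electrodes=False
    )
    _, sd_closed = probability_trace_stats(log, TRANSIENT_S)
    plant2 = make_plant(s_plant2)
    open_log = run_open_loop(
        plant2, shuffled_series(log, s_shuffle), stim_period=STIM_PERIOD,
        tau=TAU, p0=p_star, record_electrodes=False, mode="open_shuffle",
    )
    _, sd_shuffled = probability_trace_stats(open_log, TRANSIENT_S)
    return sd_closed, sd_shuffled


def amplitude_vs_setpoint(
    seed: int,
    p_low: float = 0.3,
    p_high: float = 0.7,
    duration_s: float = 2 * HOUR,
) -> tuple[float, float]:
    """Mean commanded amplitude at a low vs high set-point, paired plant seed."""
    out = []
    for p_star in (p_low, p_high):
        log, _ = closed_loop_session(
            p_star, duration_s, seed, record_electrodes=False
        )
        post = log.post_transient(TRANSIENT_S)
        out.append(float(post.amplitude_mV.mean()))
    return out[0], out[1]


def io_stability_closed_vs_open(
    seed: int, duration_s: float = 5 * HOUR, p_star: float = 0.5,
    epoch_s: float = 2400.0,
) -> tuple[float, float]:
    """Input-output stability (SD of mid-range inputs over 40 min epochs):
    closed loop on the plastic plant vs shuffled open loop on a matched plant.

    Returns (sd_closed, sd_open); larger means a less stationary curve.
    """
    s_shuffle, = child_seeds(seed, 1)
    log, _ = closed_loop_session(p_star, duration_s, seed,
                                 record_electrodes=False)
    sd_closed = io_stability(io_curves_by_epoch(log, epoch_s))
    plant2 = make_plant(seed)  # matched hidden-dynamics seed, fresh state
    open_log = run_open_loop(
        plant2, shuffled_series(log, s_shuffle), stim_period=STIM_PERIOD,
        tau=TAU, p0=p_star, record_electrodes=False, mode="open_shuffle",
    )
    sd_open = io_stability(io_curves_by_epoch(open_log, epoch_s))
    return sd_closed, sd_open


def correlation_dispersion(
    seed: int, duration_s: float = 2 * HOUR,
    p_low: float = 0.2, p_high: float = 0.7,
) -> tuple[float, float]:
    """SD of the pairwise first-spike-latency correlation distribution at a
    low vs a high set-point (matched plant seeds).

    Returns (sd_r_low, sd_r_high); high response rates drive more plastic
    dispersion and hence a broader correlation distribution.
    """
    out = []
    for p_star in (p_low, p_high):
        log, _ = closed_loop_session(p_star, duration_s, seed)
        r = pairwise_latency_correlations(log).r
        out.append(float(r.std()))
    return out[0], out[1]


def spontaneous_tradeoff(
    seed: int, duration_s: float = 2 * HOUR,
    p_low: float = 0.2, p_high: float = 0.7,
) -> pd.DataFrame:
    """Normalized spontaneous NS rate at low vs high clamped response rates.

    Rates are normalized to a no-stimulation session on a matched plant seed.
    """
    baseline = run_no_stimulation(make_plant(seed), duration_s)
    rows = []
    for p_star in (p_low, p_high):
        log, _ = closed_loop_session(
            p_star, duration_s, seed, record_electrodes=False
        )
        norm_spont, evoked = spontaneous_evoked_rates(log, baseline)
        rows.append((p_star, norm_spont, evoked))
    return pd.DataFrame(
        rows, columns=["p_star", "normalized_spontaneous_rate", "evoked_rate"]
    )
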