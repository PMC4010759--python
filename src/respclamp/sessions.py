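"""Session orchestration: closed-loop, constant/replay/shuffle open-loop runs,
amplitude scans, and baseline calibration against the synthetic plant.

A session delivers stimuli at a fixed period (default 5 s, i.e. 0.2 Hz).  Per
trial the pipeline is: look up the set-point, stimulate at the commanded
amplitude, score the response from the NS onsets falling in the post-stimulus
window (spontaneous NSs occurring between stimuli are simulated and can land in
the window, as in the real recording), update the online estimators, and
compute the next amplitude.  Open-loop modes run the identical pipeline with
the controller bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .control import (
    ControllerConfig,
    ControllerState,
    control_error,
    dual_control_step,
    pi_output,
    setpoint_value,
)
from .detection import DetectionParams, response_indicator
from .estimation import (
    EstimatorState,
    update_latency_estimate,
    update_probability_estimate,
)
from .plant import Plant, NetworkSpike

__all__ = [
    "SessionLog",
    "CalibrationError",
    "run_closed_loop",
    "run_open_loop",
    "run_no_stimulation",
    "amplitude_scan",
    "calibrate_baseline",
    "shuffled_series",
]

SCHEMA_VERSION = 1


class CalibrationError(RuntimeError):
    """Requested set-point unreachable within the scanned amplitude range."""


@dataclass
class SessionLog:
    """Per-trial records plus estimator/controller traces and NS events.

    ``trials`` columns: n, t_n_s, amplitude_mV, p_star, y, latency_ms, p_tau,
    l_tau_ms, e, integral_sum.  ``electrode_latencies`` is an
    (n_trials, n_electrodes) array of first-spike latencies in ms (NaN = no
    response / silent electrode).  ``spontaneous`` has one row per spontaneous
    NS (onset_s).  ``config`` is a JSON-serialisable snapshot sufficient to
    reproduce the run.
    """

    trials: pd.DataFrame
    electrode_latencies: np.ndarray
    spontaneous: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def start_time(self) -> float:
        return float(self.config.get("start_time", 0.0))

    def post_transient(self, discard_s: float) -> pd.DataFrame:
        """Trials after the first ``discard_s`` seconds of the session."""
        t0 = self.start_time + discard_s
        return self.trials[self.trials.t_n_s >= t0]


def _empty_spont() -> pd.DataFrame:
    return pd.DataFrame({"onset_s": pd.Series(dtype=float)})


def _score_trial(
    ns: Optional[NetworkSpike],
    spont: list[NetworkSpike],
    t_n: float,
    det: DetectionParams,
) -> tuple[int, Optional[float], Optional[NetworkSpike], list[NetworkSpike]]:
    """y(n), latency, and the NS that produced the response (if any).

    Spontaneous NSs within the detector refractory of the evoked onset are
    dropped (a real network cannot fire two NSs that close).
    """
    events = list(spont)
    if ns is not None:
        refr = det.refractory / 1000.0
        events = [s for s in events if abs(s.onset - ns.onset) >= refr]
        events.append(ns)
    events.sort(key=lambda ev: ev.onset)
    y, lat = response_indicator([ev.onset for ev in events], t_n, det)
    responder = None
    if y:
        for ev in events:
            if abs((ev.onset - t_n) * 1000.0 - lat) < 1e-9:
                responder = ev
                break
    return y, lat, responder, events


def _run_session(
    plant: Plant,
    n_trials: int,
    amplitude_fn,
    setpoint_fn,
    tau: float,
    stim_period: float,
    detection: DetectionParams,
    p0: Optional[float],
    record_electrodes: bool,
    config: dict,
) -> SessionLog:
    start = plant.state.clock
    est = EstimatorState(
        p_tau=p0 if p0 is not None else setpoint_fn(start + stim_period),
        tau=tau,
        last_time=start,
    )
    n_elec = plant.config.n_electrodes
    elec = (
        np.full((n_trials, n_elec), np.nan) if record_electrodes else
        np.empty((0, n_elec))
    )
    cols = {k: np.empty(n_trials) for k in
            ("t_n_s", "amplitude_mV", "p_star", "p_tau", "e", "integral_sum")}
    y_arr = np.zeros(n_trials, dtype=int)
    lat_arr = np.full(n_trials, np.nan)
    ltau_arr = np.full(n_trials, np.nan)
    spont_onsets: list[float] = []

    for n in range(n_trials):
        t_n = start + (n + 1) * stim_period
        p_star = setpoint_fn(t_n)
        amp = amplitude_fn(n, t_n, est)
        ns = plant.respond(amp, t_n, stimulus_index=n)
        spont = plant.spontaneous(t_n, t_n + stim_period)
        y, lat, responder, _ = _score_trial(ns, spont, t_n, detection)
        spont_onsets.extend(s.onset for s in spont)
        est = update_probability_estimate(est, y, t_n)
        est = update_latency_estimate(est, lat, t_n)
        if record_electrodes and responder is not None:
            if responder.evoked:
                elec[n] = responder.first_spike_latencies
            else:  # spontaneous NS in the window: re-reference to the stimulus
                elec[n] = (
                    responder.first_spike_latencies
                    + (responder.onset - t_n) * 1000.0
                )
        cols["t_n_s"][n] = t_n
        cols["amplitude_mV"][n] = amp
        cols["p_star"][n] = p_star
        cols["p_tau"][n] = est.p_tau
        y_arr[n] = y
        lat_arr[n] = np.nan if lat is None else lat
        ltau_arr[n] = np.nan if est.l_tau is None else est.l_tau
        cols["e"][n], cols["integral_sum"][n] = _controller_trace(amplitude_fn)

    trials = pd.DataFrame(
        {
            "n": np.arange(n_trials),
            "t_n_s": cols["t_n_s"],
            "amplitude_mV": cols["amplitude_mV"],
            "p_star": cols["p_star"],
            "y": y_arr,
            "latency_ms": lat_arr,
            "p_tau": cols["p_tau"],
            "l_tau_ms": ltau_arr,
            "e": cols["e"],
            "integral_sum": cols["integral_sum"],
        }
    )
    spont_df = pd.DataFrame({"onset_s": np.asarray(spont_onsets, dtype=float)})
    cfg = dict(config)
    cfg.update(
        schema_version=SCHEMA_VERSION,
        start_time=start,
        stim_period=stim_period,
        tau=tau,
        n_trials=n_trials,
        duration_s=n_trials * stim_period,
        n_electrodes=n_elec,
    )
    return SessionLog(trials, elec, spont_df, cfg)


def _controller_trace(amplitude_fn) -> tuple[float, float]:
    state = getattr(amplitude_fn, "ctrl_state", None)
    if state is None:
        return np.nan, np.nan
    return state.last_error, state.integral_sum


def run_closed_loop(
    plant: Plant,
    controller: ControllerConfig,
    duration_s: float,
    stim_period: float = 5.0,
    tau: float = 250.0,
    detection: DetectionParams = DetectionParams(),
    dual_control_start: Optional[float] = None,
    p0: Optional[float] = None,
    record_electrodes: bool = True,
) -> SessionLog:
    """Closed-loop response clamp for ``duration_s`` seconds.

    The estimator is initialised at the set-point (unless ``p0`` is given), so
    the loop starts at zero error rather than with a warm-up transient.  If
    ``dual_control_start`` is set, trials from that session time onward use the
    combined probability+latency error.
    """
    if duration_s <= 0 or stim_period <= 0:
        raise ValueError("duration_s and stim_period must be > 0")
    n_trials = int(round(duration_s / stim_period))
    sched = controller.setpoint
    ctrl_state = ControllerState(last_output=controller.a_baseline)

    def amplitude_fn(n, t_n, est):
        nonlocal ctrl_state
        if n == 0:
            amp = min(max(controller.a_baseline, controller.a_min), controller.a_max)
            amplitude_fn.ctrl_state = ctrl_state
            return amp
        # amplitude for trial n is computed from the estimate after trial n-1
        t_prev = t_n - stim_period
        e_prob = control_error(setpoint_value(sched, t_prev), est.p_tau)
        dual = (
            dual_control_start is not None
            and (t_prev - plant_start) >= dual_control_start
        )
        if dual:
            amp, ctrl_state = dual_control_step(controller, ctrl_state, e_prob, est.l_tau)
        else:
            amp, ctrl_state = pi_output(controller, ctrl_state, e_prob)
        amplitude_fn.ctrl_state = ctrl_state
        return amp

    plant_start = plant.state.clock
    cfg = {
        "mode": "closed",
        "plant": plant.config.to_dict(),
        "controller": {
            "g_p": controller.g_p,
            "g_i": controller.g_i,
            "a_baseline": controller.a_baseline,
            "a_min": controller.a_min,
            "a_max": controller.a_max,
            "integral_enabled": controller.integral_enabled,
            "latency_weight": controller.latency_weight,
            "latency_band": list(controller.latency_band),
            "setpoint": {
                "kind": sched.kind,
                "base": sched.base,
                "sine_amplitude": sched.sine_amplitude,
                "sine_period": sched.sine_period,
                "segments": [list(s) for s in sched.segments],
            },
        },
        "dual_control_start": dual_control_start,
    }
    return _run_session(
        plant, n_trials, amplitude_fn, lambda t: setpoint_value(sched, t),
        tau, stim_period, detection, p0, record_electrodes, cfg
    )


def run_open_loop(
    plant: Plant,
    amplitudes: Sequence[float] | np.ndarray,
    stim_period: float = 5.0,
    tau: float = 250.0,
    detection: DetectionParams = DetectionParams(),
    p0: float = 0.5,
    record_electrodes: bool = True,
    mode: str = "open",
) -> SessionLog:
    """Open-loop session: the controller is bypassed, amplitudes are given.

    Use a length-1 broadcast for constant-amplitude sessions, a closed-loop
    log's amplitude column for replay, or :func:`shuffled_series` for the
    shuffled control.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.ndim != 1 or amps.size == 0:
        raise ValueError("amplitudes must be a non-empty 1-D series")
    n_trials = amps.size

    def amplitude_fn(n, t_n, est):
        return float(amps[n])

    cfg = {"mode": mode, "plant": plant.config.to_dict()}
    return _run_session(
        plant, n_trials, amplitude_fn, lambda t: np.nan,
        tau, stim_period, detection, p0, record_electrodes, cfg
    )


def run_no_stimulation(
    plant: Plant, duration_s: float, dt: float = 5.0
) -> SessionLog:
    """Record spontaneous NSs only (baseline for rate normalisation).

    The hidden dynamics are advanced in ``dt`` steps so drift statistics match
    stimulated sessions.
    """
    start = plant.state.clock
    onsets: list[float] = []
    t = start
    while t < start + duration_s - 1e-9:
        step = min(dt, start + duration_s - t)
        onsets.extend(s.onset for s in plant.spontaneous(t, t + step))
        plant.drift_step(step)
        t += step
    trials = pd.DataFrame(
        {
            "n": pd.Series(dtype=int),
            "t_n_s": pd.Series(dtype=float),
            "amplitude_mV": pd.Series(dtype=float),
            "p_star": pd.Series(dtype=float),
            "y": pd.Series(dtype=int),
            "latency_ms": pd.Series(dtype=float),
            "p_tau": pd.Series(dtype=float),
            "l_tau_ms": pd.Series(dtype=float),
            "e": pd.Series(dtype=float),
            "integral_sum": pd.Series(dtype=float),
        }
    )
    cfg = {
        "mode": "no_stimulation",
        "plant": plant.config.to_dict(),
        "schema_version": SCHEMA_VERSION,
        "start_time": start,
        "stim_period": dt,
        "tau": np.nan,
        "n_trials": 0,
        "duration_s": duration_s,
        "n_electrodes": plant.config.n_electrodes,
    }
    return SessionLog(
        trials,
        np.empty((0, plant.config.n_electrodes)),
        pd.DataFrame({"onset_s": np.asarray(onsets, dtype=float)}),
        cfg,
    )


def shuffled_series(log: SessionLog, seed: int) -> np.ndarray:
    """Seeded permutation of a closed-loop log's amplitude series."""
    rng = np.random.default_rng(seed)
    return rng.permutation(log.trials.amplitude_mV.to_numpy())


def amplitude_scan(
    plant: Plant,
    amplitudes: Optional[Sequence[float]] = None,
    repeats: int = 10,
    stim_period: float = 5.0,
) -> pd.DataFrame:
    """Randomized-order amplitude scan (100-900 mV in 50 mV steps by default).

    Returns one row per amplitude: n_trials, response_fraction (fraction of
    stimuli that evoked an NS) and mean evoked latency in ms.
    """
    if repeats < 10:
        raise ValueError("repeats must be >= 10 (at least 10 responses per value)")
    if amplitudes is None:
        amplitudes = np.arange(100.0, 901.0, 50.0)
    amps = np.repeat(np.asarray(amplitudes, dtype=float), repeats)
    order = plant.rng.permutation(amps.size)
    amps = amps[order]
    rows = []
    t = plant.state.clock
    for a in amps:
        t += stim_period
        ns = plant.respond(a, t)
        rows.append((a, 1 if ns is not None else 0,
                     ns.latency if ns is not None else np.nan))
    df = pd.DataFrame(rows, columns=["amplitude_mV", "y", "latency_ms"])
    out = (
        df.groupby("amplitude_mV")
        .agg(
            n_trials=("y", "size"),
            response_fraction=("y", "mean"),
            mean_latency_ms=("latency_ms", "mean"),
        )
        .reset_index()
    )
    return out


def calibrate_baseline(
    plant: Plant,
    p_star: float,
    repeats: int = 25,
    amplitudes: Optional[Sequence[float]] = None,
) -> float:
    """Open-loop baseline amplitude for a desired response probability.

    Runs an amplitude scan on a clone of the plant (so calibration does not
    advance the session plant's clock or plasticity), fits the Boltzmann curve,
    and inverts it at ``p_star``.
    """
    from .analysis import fit_boltzmann

    if not 0.0 < p_star < 1.0:
        raise CalibrationError("p_star must be in (0, 1)")
    scan = amplitude_scan(plant.clone(), amplitudes=amplitudes, repeats=repeats)
    frac = scan.response_fraction.to_numpy()
    if not (frac.min() <= p_star <= frac.max()):
        raise CalibrationError(
            f"p_star={p_star} outside the scanned response range "
            f"[{frac.min():.2f}, {frac.max():.2f}]"
        )
    a50, k = fit_boltzmann(
        scan.amplitude_mV.to_numpy(), frac, scan.n_trials.to_numpy()
    )
    baseline = a50 + k * np.log(p_star / (1.0 - p_star))
    if not (100.0 <= baseline <= 1000.0):
        raise CalibrationError(
            f"calibrated baseline {baseline:.0f} mV outside the stimulator range"
        )
    return float(baseline)
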