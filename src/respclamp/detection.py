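"""Network-spike detection and response-feature extraction from spike rasters.

An NS is declared when the array-wide spike rate crosses threshold: the trailing
25 ms window reaching 20 spikes, with a 500 ms refractory period between
detections.  The NS onset is the time of the spike at which the trailing count
first reaches threshold (an event-driven crossing rather than fixed bin
partitions, which would split bursts at bin edges).

A stimulus is scored as responded (y = 1) when an NS onset falls inside the
half-open post-stimulus window [10, 800) ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DetectionParams",
    "detect_network_spikes",
    "response_indicator",
    "first_spike_latencies",
    "ppsth",
]


@dataclass
class DetectionParams:
    bin_width: float = 25.0        # ms, trailing window for the rate threshold
    spike_threshold: int = 20      # spikes across the array within the window
    refractory: float = 500.0      # ms between accepted NS onsets
    response_window: tuple[float, float] = (10.0, 800.0)  # ms, half-open

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.spike_threshold < 1:
            raise ValueError("spike_threshold must be >= 1")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        lo, hi = self.response_window
        if not lo < hi:
            raise ValueError("response_window lower bound must be below upper")


def _raster_times(raster) -> np.ndarray:
    """Spike times (s) from an (n, 2) array of (electrode_id, time_s) rows."""
    arr = np.asarray(raster, dtype=float)
    if arr.size == 0:
        return np.empty(0)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("raster must be an (n, 2) array of (electrode_id, time_s)")
    return np.sort(arr[:, 1])


def detect_network_spikes(
    raster, params: DetectionParams = DetectionParams()
) -> np.ndarray:
    """NS onset times (s) from a spike raster.

    The trailing window is half-open, (t - bin_width, t]; a crossing is accepted
    only if at least ``refractory`` ms have elapsed since the previous accepted
    onset.  Output is invariant to the input ordering of spike events.
    """
    times = _raster_times(raster)
    if times.size == 0:
        return np.empty(0)
    w = params.bin_width / 1000.0
    refr = params.refractory / 1000.0
    onsets = []
    j = 0
    last = -np.inf
    for i in range(times.size):
        while times[j] <= times[i] - w:
            j += 1
        if i - j + 1 >= params.spike_threshold and times[i] - last >= refr:
            onsets.append(times[i])
            last = times[i]
    return np.asarray(onsets)


def response_indicator(
    ns_onsets: Sequence[float] | np.ndarray,
    t_n: float,
    params: DetectionParams = DetectionParams(),
) -> tuple[int, Optional[float]]:
    """Binary response y(n) and latency (ms) for the stimulus at ``t_n`` (s).

    y = 1 iff an NS onset falls in [t_n + lo, t_n + hi) ms; latency is then the
    first such onset minus t_n, in ms.
    """
    onsets = np.asarray(ns_onsets, dtype=float)
    if onsets.size == 0:
        return 0, None
    lo, hi = params.response_window
    lat_ms = (np.sort(onsets) - t_n) * 1000.0
    eps = 1e-6  # absorb float error at the window edges
    in_win = lat_ms[(lat_ms >= lo - eps) & (lat_ms < hi - eps)]
    if in_win.size == 0:
        return 0, None
    return 1, float(in_win[0])


def first_spike_latencies(
    raster,
    t_n: float,
    n_electrodes: int,
    t_next: Optional[float] = None,
) -> np.ndarray:
    """Per-electrode time to first spike after ``t_n``, in ms (NaN if silent).

    Spikes at or after ``t_next`` (the following stimulus) are ignored.
    """
    arr = np.asarray(raster, dtype=float)
    out = np.full(n_electrodes, np.nan)
    if arr.size == 0:
        return out
    mask = arr[:, 1] > t_n
    if t_next is not None:
        mask &= arr[:, 1] < t_next
    sel = arr[mask]
    for e in range(n_electrodes):
        t_e = sel[sel[:, 0] == e, 1]
        if t_e.size:
            out[e] = (t_e.min() - t_n) * 1000.0
    return out


def ppsth(
    raster,
    stimuli: Sequence[float] | np.ndarray,
    bin_ms: float = 5.0,
    window_ms: float = 800.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Population post-stimulus time histogram, summed over stimuli.

    Returns (bin_edges_ms, counts); all spikes across electrodes falling in
    [0, window_ms) after each stimulus are counted.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    edges = np.arange(0.0, window_ms + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    arr = np.asarray(raster, dtype=float)
    if arr.size:
        for t_s in np.asarray(stimuli, dtype=float):
            rel = (arr[:, 1] - t_s) * 1000.0
            sel = rel[(rel >= 0.0) & (rel < window_ms)]
            counts += np.histogram(sel, bins=edges)[0]
    return edges, counts
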