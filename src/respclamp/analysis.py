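"""Summary statistics of clamp sessions: fluctuation quantification,
input-output curves and their stability, pairwise first-spike-latency
correlations, and the spontaneous/evoked rate tradeoff.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .plant import boltzmann

__all__ = [
    "IOCurve",
    "FitError",
    "probability_trace_stats",
    "fit_boltzmann",
    "io_curve",
    "io_curves_by_epoch",
    "io_stability",
    "pairwise_latency_correlations",
    "spontaneous_evoked_rates",
]


class FitError(RuntimeError):
    """Boltzmann fit failed or the data cannot identify the curve."""


@dataclass
class IOCurve:
    """Empirical input-output relation over one session epoch.

    ``bin_centers`` are 5 mV amplitude-bin centers with at least the minimum
    trial count; ``fractions`` the per-bin response probabilities P_i.
    ``a50``/``k`` hold the Boltzmann fit when one was possible.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    epoch: tuple[float, float]
    a50: Optional[float] = None
    k: Optional[float] = None

    @property
    def empty(self) -> bool:
        return self.bin_centers.size == 0


def probability_trace_stats(log, discard_s: float = 500.0) -> tuple[float, float]:
    """Mean and SD of the P_tau trace after an initial transient.

    The default discard of 2*tau = 500 s removes the estimator warm-up, which
    would otherwise dominate the SD.
    """
    post = log.post_transient(discard_s)
    if len(post) == 0:
        raise ValueError("no trials remain after the transient discard")
    p = post.p_tau.to_numpy()
    return float(p.mean()), float(p.std())


def fit_boltzmann(
    amplitudes: Sequence[float],
    fractions: Sequence[float],
    counts: Sequence[float],
) -> tuple[float, float]:
    """Weighted least-squares Boltzmann fit P(A) = 1/(1 + exp((A50 - A)/k)).

    Bin counts enter as inverse-variance-style weights (sigma ~ 1/sqrt(n)).
    Returns (A50, k) in mV; raises :class:`FitError` when the data span too
    little of the probability range to identify the curve or the optimiser
    fails.
    """
    a = np.asarray(amplitudes, dtype=float)
    f = np.asarray(fractions, dtype=float)
    n = np.asarray(counts, dtype=float)
    if a.size < 3:
        raise FitError("need at least 3 amplitude bins")
    if f.max() - f.min() <= 0.2:
        raise FitError(
            f"response fractions span only {f.max() - f.min():.2f}; "
            "curve not identifiable"
        )
    # initial guesses: midpoint from the fraction closest to 0.5, slope from
    # the amplitude spread of the transition region
    a50_0 = a[np.argmin(np.abs(f - 0.5))]
    trans = a[(f > 0.1) & (f < 0.9)]
    k0 = max((trans.max() - trans.min()) / 4.0, 1.0) if trans.size >= 2 else \
        max((a.max() - a.min()) / 10.0, 1.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, a50, k: boltzmann(x, a50, k),
                a, f,
                p0=(a50_0, k0),
                sigma=1.0 / np.sqrt(np.maximum(n, 1.0)),
                bounds=((a.min() - 500.0, 1e-3), (a.max() + 500.0, 1e4)),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])


def io_curve(
    log,
    epoch: tuple[float, float],
    bin_mv: float = 5.0,
    min_count: int = 10,
    fit: bool = True,
) -> IOCurve:
    """Input-output relation over ``epoch`` (absolute session times, s).

    Amplitudes are binned to ``bin_mv``; bins with fewer than ``min_count``
    trials are excluded.  A Boltzmann fit is attached when identifiable.
    """
    t = log.trials
    sel = t[(t.t_n_s >= epoch[0]) & (t.t_n_s < epoch[1])]
    if len(sel) == 0:
        return IOCurve(np.empty(0), np.empty(0), np.empty(0), epoch)
    amp = sel.amplitude_mV.to_numpy()
    y = sel.y.to_numpy()
    idx = np.floor(amp / bin_mv).astype(int)
    centers, counts, fracs = [], [], []
    for b in np.unique(idx):
        m = idx == b
        if m.sum() >= min_count:
            centers.append((b + 0.5) * bin_mv)
            counts.append(int(m.sum()))
            fracs.append(float(y[m].mean()))
    curve = IOCurve(
        np.asarray(centers), np.asarray(counts, dtype=float),
        np.asarray(fracs), epoch
    )
    if fit and not curve.empty:
        try:
            curve.a50, curve.k = fit_boltzmann(
                curve.bin_centers, curve.fractions, curve.counts
            )
        except FitError:
            pass
    return curve


def io_curves_by_epoch(
    log, epoch_s: float = 2400.0, bin_mv: float = 5.0, min_count: int = 10
) -> list[IOCurve]:
    """Contiguous fixed-length epochs (default 40 min) from session start."""
    t0 = log.start_time
    t_end = float(log.trials.t_n_s.max())
    curves = []
    while t0 + epoch_s <= t_end + 1e-9:
        curves.append(io_curve(log, (t0, t0 + epoch_s), bin_mv, min_count))
        t0 += epoch_s
    return curves


def io_stability(curves: Sequence[IOCurve]) -> float:
    """SD (mV) of mid-range inputs across epochs.

    Collects every amplitude-bin center whose response fraction lies strictly
    inside (0.45, 0.55) across all epochs and returns their standard
    deviation — small when the input-output curve is stationary, inflated when
    it drifts.  Returns NaN when no bin qualifies.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 epochs")
    mids = []
    for c in curves:
        if c.empty:
            continue
        band = (c.fractions > 0.45) & (c.fractions < 0.55)
        mids.extend(c.bin_centers[band])
    if not mids:
        return float("nan")
    return float(np.std(np.asarray(mids)))


def pairwise_latency_correlations(
    log,
    valid_range: tuple[float, float] = (10.0, 400.0),
    min_shared: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of first-spike latencies for every electrode pair.

    Latencies outside [10, 400] ms are discarded; a pair contributes only if
    both electrodes are valid on at least ``min_shared`` common trials
    (listwise deletion per pair).  Returns columns (electrode_a, electrode_b,
    r, n_shared).
    """
    lat = np.asarray(log.electrode_latencies, dtype=float)
    lo, hi = valid_range
    valid = (lat >= lo) & (lat <= hi)
    n_elec = lat.shape[1] if lat.ndim == 2 else 0
    rows = []
    for i, j in itertools.combinations(range(n_elec), 2):
        shared = valid[:, i] & valid[:, j]
        if shared.sum() < min_shared:
            continue
        xi, xj = lat[shared, i], lat[shared, j]
        if xi.std() == 0.0 or xj.std() == 0.0:
            continue
        r = float(np.corrcoef(xi, xj)[0, 1])
        rows.append((i, j, r, int(shared.sum())))
    return pd.DataFrame(rows, columns=["electrode_a", "electrode_b", "r", "n_shared"])


def spontaneous_evoked_rates(log, baseline_log) -> tuple[float, float]:
    """(normalized spontaneous rate, evoked NSs per stimulus).

    The spontaneous NS rate during the stimulated session is divided by the
    spontaneous rate of a no-stimulation baseline on a matched plant; the
    evoked rate is the fraction of stimuli that produced a response.
    """
    def _spont_rate(lg) -> float:
        dur = lg.config.get(
            "duration_s",
            lg.config.get("n_trials", len(lg.trials))
            * lg.config.get("stim_period", 5.0),
        )
        if dur <= 0:
            return float("nan")
        return len(lg.spontaneous) / dur

    base = _spont_rate(baseline_log)
    if not np.isfinite(base) or base == 0.0:
        return float("nan"), float(log.trials.y.mean()) if len(log.trials) else float("nan")
    return _spont_rate(log) / base, float(log.trials.y.mean())
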