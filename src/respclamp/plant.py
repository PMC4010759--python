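"""Stochastic surrogate of a cultured cortical network on a multi-electrode array.

The plant stands in for the biological preparation in closed-loop experiments.
It is deliberately phenomenological: a Boltzmann (logistic) stimulus-amplitude →
response-probability curve whose midpoint carries three hidden processes —

* a mean-reverting (Ornstein–Uhlenbeck) excitability drift with a minutes-scale
  relaxation time, producing the slow response-probability fluctuations seen
  under constant-amplitude stimulation;
* an activity-dependent, irreversible rightward plastic shift (one fixed
  increment per evoked network spike);
* a short-term resource that is depleted by each network spike and recovers
  exponentially, multiplying response probability.

Evoked network-spike (NS) latency decreases monotonically with amplitude via a
descending logistic sharing the probability curve's midpoint and slope, plus an
independent OU drift of its own and Gaussian jitter.  Each electrode carries a
latency offset that takes an independent random-walk step per evoked NS, so
sustained high response rates disperse the pairwise structure of first-spike
latencies.  Spontaneous NSs occur as a Poisson process whose rate is suppressed
by recent evoked activity.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "PlantConfig",
    "PlantState",
    "NetworkSpike",
    "Plant",
    "PlantConfigError",
    "PlantDomainError",
    "boltzmann",
]

#: reference evoked-NS rate (NS/s) used to scale spontaneous-rate suppression;
#: equals the evoked rate of a p = 0.5 clamp at the standard 0.2 Hz stimulation.
SUPPRESSION_RATE_SCALE = 0.1


class PlantConfigError(ValueError):
    """Invalid plant configuration."""


class PlantDomainError(ValueError):
    """Stimulation request outside the plant's physical domain."""


def boltzmann(amplitude: np.ndarray | float, a50: float, k: float):
    """Boltzmann response curve P(A) = 1 / (1 + exp((A50 - A)/k))."""
    return 1.0 / (1.0 + np.exp((a50 - np.asarray(amplitude, dtype=float)) / k))


@dataclass
class PlantConfig:
    """Calibration of the synthetic network.

    Defaults reproduce the qualitative phenomenology of dissociated cortical
    cultures under 0.2 Hz stimulation: a steep sigmoid centred at 350 mV,
    open-loop probability fluctuations with SD ~ 0.2 over hours, closed-loop
    residual SD in the 0.02-0.03 band with the standard PI gains, a rightward
    plastic creep of tens of mV over a multi-hour high-rate session, and a
    spontaneous NS every ~50 s when unstimulated.
    """

    n_electrodes: int = 60
    a50_0: float = 350.0           # Boltzmann midpoint, mV
    k_slope: float = 20.0          # Boltzmann slope, mV
    latency_base: float = 15.0     # ms, latency floor at strong amplitudes
    latency_gain: float = 8.0      # ms, latency excess at the midpoint A50
    latency_slope: float = 10.0    # mV, e-fold length of the latency decay
    latency_cap: float = 400.0     # ms, ceiling of the deterministic latency
    latency_jitter_sd: float = 6.0  # ms, NS-level and per-electrode jitter
    drift_sd: float = 1.5          # mV * s^-1/2, OU diffusion of the midpoint
    drift_relaxation: float = 900.0    # s, OU relaxation time of the midpoint
    latency_drift_sd: float = 0.024    # s^-1/2, log-space OU diffusion of latency
    latency_drift_relaxation: float = 900.0  # s
    plasticity_rate: float = 0.04  # mV rightward shift per evoked NS
    dispersion_rate: float = 0.5   # ms random-walk step SD per evoked NS
    spont_rate_0: float = 0.02     # NS/s with no recent evoked activity
    suppression_gain: float = 2.0  # dimensionless
    resource_depletion: float = 0.02   # fraction of resource spent per NS
    resource_recovery: float = 30.0    # s, resource recovery time constant
    electrode_participation: float = 0.9  # P(electrode fires in a given NS)
    offset_sd: float = 5.0         # ms, SD of initial electrode offsets
    evoked_rate_tau: float = 120.0  # s, smoothing of the evoked-rate tracker
    seed: int = 0

    #: hard floor on evoked NS latency, ms: burst ignition and spread are never
    #: faster than this, whatever the drift state
    LATENCY_FLOOR_MS = 12.0

    def validate(self) -> None:
        if self.n_electrodes < 2:
            raise PlantConfigError("n_electrodes must be >= 2")
        if not (100.0 <= self.a50_0 <= 900.0):
            raise PlantConfigError("a50_0 must lie in [100, 900] mV")
        if self.k_slope <= 0:
            raise PlantConfigError("k_slope must be > 0")
        if self.latency_slope <= 0 or self.latency_cap <= 0:
            raise PlantConfigError("latency_slope and latency_cap must be > 0")
        nonneg = (
            "latency_base latency_gain latency_jitter_sd drift_sd "
            "drift_relaxation latency_drift_sd latency_drift_relaxation "
            "plasticity_rate dispersion_rate spont_rate_0 suppression_gain "
            "resource_depletion resource_recovery offset_sd evoked_rate_tau"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise PlantConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.electrode_participation <= 1.0):
            raise PlantConfigError("electrode_participation must be in [0, 1]")
        if not (0.0 <= self.resource_depletion < 1.0):
            raise PlantConfigError("resource_depletion must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PlantState:
    """Hidden variables of the surrogate network."""

    clock: float = 0.0             # s
    a50_drift: float = 0.0         # mV, OU component of the midpoint
    latency_drift: float = 0.0     # ms, OU component of latency
    plastic_shift: float = 0.0     # mV, cumulative (nonnegative)
    resource: float = 1.0          # in [0, 1]
    evoked_count: int = 0
    evoked_rate: float = 0.0       # NS/s, kernel-smoothed
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class NetworkSpike:
    """One network spike: a synchronous burst spreading across the array."""

    onset: float                   # s
    evoked: bool
    stimulus_index: Optional[int] = None
    latency: Optional[float] = None  # ms after the stimulus, evoked only
    first_spike_latencies: Optional[np.ndarray] = None  # ms, NaN = silent

    def __post_init__(self):
        if self.evoked and (self.latency is None or self.latency <= 0):
            raise ValueError("evoked NS requires a positive latency")


class Plant:
    """Stateful synthetic network; all randomness flows from ``config.seed``."""

    def __init__(self, config: PlantConfig):
        config.validate()
        self.config = config
        # independent streams: hidden drift consumes a fixed draw count per
        # unit time, so two sessions with the same seed share the same drift
        # path even when their stimulation (and hence response draws) differ
        drift_ss, resp_ss, spont_ss = np.random.SeedSequence(config.seed).spawn(3)
        self.rng_drift = np.random.default_rng(drift_ss)
        self.rng = np.random.default_rng(resp_ss)
        self.rng_spont = np.random.default_rng(spont_ss)
        self.state = PlantState(
            offsets=self.rng.normal(0.0, config.offset_sd, config.n_electrodes)
        )

    # -- hidden-state dynamics -------------------------------------------------

    @property
    def a50_eff(self) -> float:
        """Current effective midpoint: baseline + drift + plastic shift."""
        return self.config.a50_0 + self.state.a50_drift + self.state.plastic_shift

    def clone(self) -> "Plant":
        """Deep copy, including RNG state (used for non-invasive calibration)."""
        return copy.deepcopy(self)

    def _ou_step(self, x: float, dt: float, sd: float, relax: float) -> float:
        # exact OU transition: stationary SD = sd * sqrt(relax / 2)
        if sd == 0.0:
            return x * math.exp(-dt / relax) if relax > 0 else x
        a = math.exp(-dt / relax)
        step_sd = sd * math.sqrt(relax / 2.0 * (1.0 - a * a))
        return a * x + step_sd * self.rng_drift.standard_normal()

    def drift_step(self, dt: float) -> None:
        """Advance hidden dynamics by ``dt`` seconds (drift, recovery, decay)."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        c, s = self.config, self.state
        s.a50_drift = self._ou_step(s.a50_drift, dt, c.drift_sd, c.drift_relaxation)
        s.latency_drift = self._ou_step(
            s.latency_drift, dt, c.latency_drift_sd, c.latency_drift_relaxation
        )
        if c.resource_recovery > 0:
            s.resource = 1.0 - (1.0 - s.resource) * math.exp(-dt / c.resource_recovery)
        s.evoked_rate *= math.exp(-dt / c.evoked_rate_tau)
        s.clock += dt

    def _advance_to(self, t: float) -> None:
        if t < self.state.clock:
            raise ValueError("time must not run backwards")
        if t > self.state.clock:
            self.drift_step(t - self.state.clock)

    def plasticity_step(self, evoked: bool) -> None:
        """Per-trial plastic update: rightward midpoint creep and offset walk."""
        if not evoked:
            return
        c, s = self.config, self.state
        s.plastic_shift += c.plasticity_rate
        if c.dispersion_rate > 0:
            s.offsets = s.offsets + self.rng.normal(
                0.0, c.dispersion_rate, c.n_electrodes
            )

    # -- responses -------------------------------------------------------------

    def response_probability(self, amplitude: float) -> float:
        """True (hidden) probability of evoking an NS at this instant."""
        return self.state.resource * float(
            boltzmann(amplitude, self.a50_eff, self.config.k_slope)
        )

    def mean_latency(self, amplitude: float) -> float:
        """Deterministic part of evoked latency, ms; monotone decreasing in A.

        Exponential decay with amplitude above threshold — stronger drive
        recruits the burst faster — with a short e-fold length, so latency is
        considerably more amplitude-sensitive than response probability.  The
        drift acts multiplicatively (log-space OU): latency is positive and
        its slow wander scales with its current magnitude.
        """
        c = self.config
        arg = -(amplitude - self.a50_eff) / c.latency_slope + self.state.latency_drift
        excess = c.latency_gain * math.exp(min(arg, 12.0))
        return c.latency_base + min(excess, c.latency_cap)

    def _electrode_latencies(self, ns_latency: float, rng=None) -> np.ndarray:
        c = self.config
        rng = self.rng if rng is None else rng
        lat = (
            ns_latency
            + self.state.offsets
            + rng.normal(0.0, c.latency_jitter_sd, c.n_electrodes)
        )
        participating = rng.random(c.n_electrodes) < c.electrode_participation
        lat = np.clip(lat, 1.0, None)
        lat[~participating] = np.nan
        return lat

    def respond(
        self, amplitude: float, t: float, stimulus_index: Optional[int] = None
    ) -> Optional[NetworkSpike]:
        """Stimulate at time ``t`` (s) and amplitude (mV); maybe evoke an NS.

        Advances hidden dynamics to ``t``, draws the response, and applies the
        per-trial resource and plasticity updates.
        """
        if not (100.0 <= amplitude <= 1000.0):
            raise PlantDomainError(
                f"amplitude {amplitude} mV outside the 100-1000 mV stimulator range"
            )
        self._advance_to(t)
        c, s = self.config, self.state
        p = self.response_probability(amplitude)
        evoked = bool(self.rng.random() < p)
        ns = None
        if evoked:
            latency = self.mean_latency(amplitude) + self.rng.normal(
                0.0, c.latency_jitter_sd
            )
            latency = max(latency, PlantConfig.LATENCY_FLOOR_MS)
            ns = NetworkSpike(
                onset=t + latency / 1000.0,
                evoked=True,
                stimulus_index=stimulus_index,
                latency=latency,
                first_spike_latencies=self._electrode_latencies(latency),
            )
            s.resource *= 1.0 - c.resource_depletion
            s.evoked_count += 1
            s.evoked_rate += 1.0 / c.evoked_rate_tau
        self.plasticity_step(evoked)
        return ns

    def spontaneous_rate(self) -> float:
        """Current spontaneous-NS rate (NS/s), suppressed by evoked activity."""
        c = self.config
        f = math.exp(
            -c.suppression_gain * self.state.evoked_rate / SUPPRESSION_RATE_SCALE
        )
        return c.spont_rate_0 * f

    def spontaneous(self, t0: float, t1: float) -> list[NetworkSpike]:
        """Spontaneous NSs in [t0, t1): Poisson at the current suppressed rate.

        The rate is held constant over the interval (intervals in the stimulation
        pipeline are one stimulation period, short against the rate tracker).
        Spontaneous NSs deplete the resource but do not drive plasticity.
        """
        if t1 <= t0:
            return []
        rate = self.spontaneous_rate()
        n = self.rng_spont.poisson(rate * (t1 - t0))
        if n == 0:
            return []
        times = np.sort(self.rng_spont.uniform(t0, t1, n))
        events = []
        for onset in times:
            events.append(
                NetworkSpike(
                    onset=float(onset),
                    evoked=False,
                    first_spike_latencies=self._electrode_latencies(
                        0.0, rng=self.rng_spont
                    ),
                )
            )
            self.state.resource *= 1.0 - self.config.resource_depletion
        return events

    # -- raster synthesis (for detector tests and pPSTHs) ----------------------

    def ns_raster(
        self, ns: NetworkSpike, spikes_per_electrode: int = 3, burst_span_ms: float = 15.0
    ) -> np.ndarray:
        """Expand an NS into spike events, rows (electrode_id, time_s).

        Each participating electrode fires its first spike at its first-spike
        latency and a few follow-up spikes within the burst envelope, so an
        isolated NS always places well over the detection threshold of spikes
        inside a 25 ms window.
        """
        lats = ns.first_spike_latencies
        base = ns.onset - (ns.latency or 0.0) / 1000.0  # stimulus/reference time
        rows = []
        for e in range(self.config.n_electrodes):
            if lats is None or np.isnan(lats[e]):
                continue
            t_first = base + lats[e] / 1000.0
            rows.append((e, t_first))
            extra = self.rng.uniform(0.5, burst_span_ms, spikes_per_electrode - 1)
            for d in np.sort(extra):
                rows.append((e, t_first + d / 1000.0))
        out = np.array(rows, dtype=float)
        return out[np.argsort(out[:, 1])] if len(out) else out.reshape(0, 2)
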