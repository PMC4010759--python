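# respclamp

Closed-loop "response clamp" of a synthetic cortical-network surrogate:
PI-feedback control of the probability (and latency) of evoked network
spikes, together with the estimation, detection and stability analyses the
paradigm needs.

Cultured cortical networks on multi-electrode arrays answer a suprathreshold
stimulus with an all-or-none synchronous burst — a **network spike (NS)** —
whose occurrence probability and latency fluctuate over minutes to hours.
A response clamp turns this into a feedback problem: after the *n*-th
stimulus, score the binary response

- y(n) = 1 if an NS onset falls in the 10–800 ms post-stimulus window,

maintain an exponentially weighted online estimate of response probability

- P_τ(n) = (1 − e^(−Δₙ/τ)) · y(n) + e^(−Δₙ/τ) · P_τ(n−1),  τ = 250 s,

and drive the next stimulation amplitude with a PI law on the error
e(n) = P\* − P_τ(n):

- A(n) = A_baseline + g_P · e(n) + g_I · Σᵢ e(i),  g_P = 400 mV, g_I = 80 mV,

clamped to the stimulator's 100–1000 mV range with anti-windup.  Because
amplitude raises response probability and shortens latency monotonically, the
same actuator can additionally hold latency inside a commanded band
(simultaneous control).

No biological recordings are involved: the **plant** is a stochastic
surrogate with a Boltzmann amplitude→probability curve whose midpoint
carries Ornstein–Uhlenbeck excitability drift, activity-dependent
(irreversible) rightward plasticity and a short-term resource, plus an
amplitude-sensitive latency law with its own multiplicative drift,
per-electrode first-spike structure, and evoked-activity-suppressed
spontaneous NSs.  This makes every claim in the pipeline testable against
known ground truth.  See `docs/methods.md` for the model and its
calibration.

## Layout

- `src/respclamp/` — the library: `plant`, `detection` (NS detector: 20
  spikes in a sliding 25 ms window, 500 ms refractory; pPSTHs; first-spike
  latencies), `estimation`, `control`, `sessions` (closed/open-loop runs,
  amplitude scans, baseline calibration), `analysis` (trace statistics,
  Boltzmann fits, input–output stability, pairwise latency correlations,
  spontaneous/evoked rates), `io` (CSV/HDF5 logs, YAML protocols), `cli`,
  and `experiments` (the canonical study batteries).
- `analysis/01…05_*.py` — numbered narrative scripts reproducing the study's
  analyses; each writes tidy CSV tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).
- `tests/` — the pytest suite.

## Worked example

```sh
$ respclamp run --p-star 0.5 --duration 7200 --seed 7 --out session.h5
wrote session.h5: 1440 trials, P_tau mean 0.499 sd 0.026
$ respclamp calibrate --p-star 0.7 --seed 7
A_baseline = 356.4 mV for P* = 0.7
```

The first command calibrates a baseline amplitude by open-loop scan, then
clamps the drifting plant at P\* = 0.5 for two hours at 0.2 Hz: the estimate
holds the set-point with SD 0.026 — an order of magnitude below the same
plant under open-loop stimulation (run `python analysis/02_quenching.py` for
the paired comparison).  The second command reports the open-loop amplitude
at which the fitted Boltzmann curve of a fresh scan crosses 0.7.

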