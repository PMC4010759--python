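# Methods

## The control problem

A cultured cortical network stimulated through a multi-electrode array either
fires a network spike (NS) or stays quiet; the per-stimulus response
probability and the NS latency drift over minutes to hours.  The response
clamp closes the loop around stimulation amplitude: score each trial's binary
response y(n) in the 10–800 ms post-stimulus window, estimate response
probability with the exponential-kernel recursion (time constant τ, default
250 s), and set the next amplitude by a PI law on e(n) = P\*(n) − P_τ(n) with
gains g_P = 400 mV and g_I = 80 mV per unit probability error, bounded to the
stimulator's 100–1000 mV range.  All session timing runs at 0.2 Hz
(5 s period).

Conventions chosen where the procedure leaves room:

- **Estimator initialisation** P_τ(0) = P\*: the loop starts at zero error
  instead of manufacturing a warm-up transient.
- **Response window** half-open, [10, 800) ms, inclusive lower edge, with a
  10⁻⁶ ms tolerance absorbing float error at the edges.
- **Refractory** of the NS detector exactly 500 ms (configurable); NS onset
  is the spike at which the trailing 25 ms count reaches 20 (event-driven
  crossing — fixed bins would split bursts at bin edges).
- **Anti-windup** by conditional integration: the integral increment is
  discarded when the output is saturated and the error pushes further into
  the bound.  An unbounded sum against a bounded actuator would otherwise
  wind up during unresponsive episodes.
- **Transient discard** of 2τ (500 s) before any summary statistic;
  estimator relaxation would otherwise dominate SDs.
- **Latency estimator**: the same exponential kernel applied over responded
  trials only (latency is undefined at y = 0), weighting by real elapsed
  time between responses; the first response initialises it.
- **Dual control** adds a band-normalized latency error to the probability
  error: zero inside the commanded band, (L_τ − nearest edge)/band width
  outside, weighted by `latency_weight` (default 1.0).  Two deliberate
  choices here: the error references the **nearest band edge** rather than
  the band center, because a center-referenced error is discontinuous at the
  edge (it jumps from 0 to 0.5) and, through g_P, hammers the plant with
  ±200 mV kicks at every crossing — in pilot runs this limit-cycled and
  *raised* latency variance; and the default weight is 1.0 so that at the
  edge a one-band-width latency excess outweighs the largest probability
  error the operating point can produce, making the band binding.

## The synthetic plant

The plant stands in for the biological preparation.  It is phenomenological
by design — no conductances, no connectivity — and aims only at the response
statistics the clamp interacts with.

**Probability.**  P(evoked) = R · Boltzmann(A; A50_eff, k) with
Boltzmann(A) = 1/(1 + exp((A50 − A)/k)).  The effective midpoint
A50_eff = A50₀ + drift + plastic shift carries:

- an Ornstein–Uhlenbeck drift (diffusion 1.5 mV·s^−1/2, relaxation 900 s,
  stationary SD ≈ 32 mV) — the minutes-scale excitability wander that makes
  open-loop response probability fluctuate with SD ≈ 0.2 over hours;
- an activity-dependent plastic shift, +0.04 mV per evoked NS, irreversible
  and rightward only — sustained evoked activity makes the network less
  sensitive;
- a short-term resource R ∈ [0, 1], multiplied into P, depleted by 2% per NS
  and recovering with a 30 s time constant.

**Latency.**  Evoked latency = 15 ms + 8 ms · exp(−(A − A50_eff)/10 mV + d)
capped at 400 ms and floored at 12 ms, plus 6 ms Gaussian jitter; d is a
log-space OU process (stationary SD 0.5, relaxation 900 s).  Three features
matter.  (i) The law is monotone decreasing in amplitude everywhere.  (ii)
Its e-fold length (10 mV) is short against the probability slope (k =
20 mV), so at any operating point latency is several times more
amplitude-sensitive than probability — this asymmetry is what lets a single
actuator serve both errors in simultaneous control; a latency curve slaved
to the probability sigmoid's slope would make dual control impossible in
principle, because clamping p would pin latency exactly.  (iii) The drift is
multiplicative, so latency stays positive and its wander scales with its
magnitude; the 12 ms floor encodes that burst ignition is never faster than
~10 ms, and keeps evoked responses inside the scoring window.

**Electrode structure.**  Each of 60 electrodes carries a latency offset
(initial SD 5 ms) that takes an independent random-walk step of SD 0.5 ms
per evoked NS; per-NS first-spike latencies are NS latency + offset + 6 ms
jitter, with each electrode participating with probability 0.9.  The walk is
the plant's mechanism for activity-dependent dispersion of pairwise
first-spike correlations: offsets diverge as √(evoked count), so high
clamped rates broaden the pairwise-r distribution.

**Spontaneous NSs.**  A Poisson process at 0.02 NS/s, multiplied by
exp(−g · r/0.1), where r is a 120 s kernel-smoothed evoked-NS rate, g = 2,
and 0.1 NS/s is the evoked rate of a p = 0.5 clamp at 0.2 Hz.  Spontaneous
NSs deplete the resource, are suppressed within the detector refractory of
an evoked NS, and — as in a real recording — count as responses when they
happen to fall inside a stimulus's scoring window.

**Randomness.**  One seed feeds three independent generators (drift,
responses, spontaneous events).  Drift consumes a fixed draw count per unit
time, so two sessions with the same plant seed traverse the *same* drift
path even under different stimulation — paired comparisons (closed vs
shuffled replay, low vs high set-point) are therefore matched on the
nuisance process they control for.  Fixed seed ⇒ bit-identical logs.

## Calibration

The defaults are frozen once, from closed-form reasoning plus pilot runs,
to reproduce the study conditions:

- **k = 20 mV, A50₀ = 350 mV.**  The closed-loop residual SD of P_τ is set
  by feedback-filtered Bernoulli estimation noise: an uncontrolled
  Bernoulli(0.5) stream smoothed with τ = 250 s at 0.2 Hz has SD
  √(p(1−p)(1−α)/(1+α)) ≈ 0.05, and the loop beats that only through the
  anticorrelation it induces, which strengthens with the plant slope at the
  operating point.  With the fixed published gains, k = 20 mV lands the
  battery at SD 0.021–0.027 — inside the reported 0.02–0.03 band — while
  flatter plants (k ≥ 40 mV) cannot reach 0.03 at P\* = 0.5 under these
  gains at all.  The resulting curve rises over ≈ 260–440 mV, within the
  scanned 100–900 mV range.
- **Drift scale** (stationary SD 32 mV ≈ 1.6 k) makes constant-amplitude
  open-loop probability fluctuate with SD ≈ 0.2 — large against the
  closed-loop residual, as in the motivating observation.
- **Plasticity rate** 0.04 mV/NS gives a ≈ 70 mV rightward creep over a 5 h
  half-responsive session — comparable to k, so the closed loop (which
  sustains evoked rates and keeps feeding the creep) visibly right-shifts
  40 min input–output curves, while under open loop the creep self-limits
  as responsiveness falls.
- **Suppression gain** 2 puts normalized spontaneous rates near 0.4–0.5 at
  P\* = 0.2 and below 0.1 at P\* = 0.7.

## What the surrogate does and does not show

Passing tests demonstrate that the algorithms are implemented correctly and
that the closed loop produces the study's phenomenology *on a plant with
these dynamics*: OU drift, Boltzmann response curve, per-NS plasticity
increments.  Real preparations have heavier-tailed nonstationarities
(development, bursts of state switching), correlated trial-to-trial
responses, electrode nonstationarity and detection noise, none of which are
modeled; quantitative values (e.g. the 0.02–0.03 SD band) transfer to
biology only insofar as the calibration above mimics it.  Latency control
results depend on the assumed probability/latency sensitivity asymmetry,
which the source preparations exhibited but which is not universal.

## Numerical notes

- Boltzmann fits: `scipy.optimize.curve_fit`, counts as inverse-variance
  weights, midpoint initialised at the half-maximum bin, slope from the
  width of the 0.1–0.9 transition; fits are refused when fractions span
  ≤ 0.2 (unidentifiable) and fit failures raise with diagnostics.
- Pairwise correlations use per-pair listwise deletion over trials where
  both electrodes have valid (10–400 ms) latencies, ≥ 10 shared trials, and
  skip zero-variance series.
- The input–output stability statistic uses strict inequalities
  (0.45 < P_i < 0.55) and 5 mV bins with ≥ 10 trials.
- OU transitions use the exact discretisation, so step size does not bias
  the stationary law.
- Problem sizes in the batteries (2–5 h sessions, 8–10 seeds) were chosen so
  every statistic's Monte-Carlo error is small against the effect it
  measures; the whole acceptance battery completes in well under a minute.

## Known limitations

- The plant's spontaneous NSs do not themselves trigger plasticity or
  latency dispersion; only evoked activity does.
- Baseline calibration scans a clone of the plant, so calibration does not
  advance the session plant's clock or plasticity — the in-vitro analogue
  (calibrating on the preparation itself) would perturb it slightly.
- The sine-tracking experiment is reproduced as traces and a tracking
  correlation only; no spectral analysis is attached.
- No derivative term, gain auto-tuning, or model-predictive extension.
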