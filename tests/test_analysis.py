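"""Analysis statistics: trace stats, Boltzmann fits, IO stability,
pairwise latency correlations, spontaneous/evoked rates."""

import numpy as np
import pandas as pd
import pytest

from respclamp.analysis import (
    FitError,
    IOCurve,
    fit_boltzmann,
    io_curve,
    io_curves_by_epoch,
    io_stability,
    pairwise_latency_correlations,
    probability_trace_stats,
    spontaneous_evoked_rates,
)
from respclamp.plant import boltzmann
from respclamp.sessions import SessionLog, run_no_stimulation
from respclamp.experiments import closed_loop_session, make_plant, HOUR


def make_log(p_tau=None, amplitudes=None, y=None, elec=None, period=5.0,
             n_spont=0, duration=None):
    """Hand-built SessionLog for oracle tests."""
    n = len(p_tau) if p_tau is not None else len(amplitudes)
    t = (np.arange(n) + 1) * period
    trials = pd.DataFrame(
        {
            "n": np.arange(n),
            "t_n_s": t,
            "amplitude_mV": amplitudes if amplitudes is not None else 300.0,
            "p_star": 0.5,
            "y": y if y is not None else 0,
            "latency_ms": np.nan,
            "p_tau": p_tau if p_tau is not None else 0.5,
            "l_tau_ms": np.nan,
            "e": 0.0,
            "integral_sum": 0.0,
        }
    )
    spont = pd.DataFrame({"onset_s": np.linspace(0.0, n * period, n_spont)})
    cfg = {
        "start_time": 0.0,
        "stim_period": period,
        "n_trials": n,
        "duration_s": duration if duration is not None else n * period,
        "n_electrodes": 0 if elec is None else elec.shape[1],
    }
    return SessionLog(
        trials, elec if elec is not None else np.empty((0, 0)), spont, cfg
    )


class TestTraceStats:
    def test_constant_trace_has_zero_sd(self):
        log = make_log(p_tau=np.full(300, 0.4))
        mean, sd = probability_trace_stats(log, discard_s=100.0)
        assert mean == pytest.approx(0.4)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sd(self):
        log = make_log(p_tau=np.array([0.4, 0.5, 0.6]))
        mean, sd = probability_trace_stats(log, discard_s=0.0)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(0.02 / 3))

    def test_empty_post_discard_rejected(self):
        log = make_log(p_tau=np.full(10, 0.5))
        with pytest.raises(ValueError):
            probability_trace_stats(log, discard_s=1e6)


class TestBoltzmannFit:
    def test_noiseless_recovery(self):
        a = np.arange(200.0, 501.0, 20.0)
        f = boltzmann(a, 340.0, 35.0)
        a50, k = fit_boltzmann(a, f, np.full(a.size, 50.0))
        assert a50 == pytest.approx(340.0, abs=1e-5)
        assert k == pytest.approx(35.0, abs=1e-5)

    def test_median_midpoint_error_under_binomial_noise(self):
        # n = 50 per bin; over 100 replicates the median |A50 error| <= 10 mV
        rng = np.random.default_rng(42)
        a = np.arange(250.0, 451.0, 10.0)
        p = boltzmann(a, 350.0, 20.0)
        errors = []
        for _ in range(100):
            f = rng.binomial(50, p) / 50.0
            a50, _ = fit_boltzmann(a, f, np.full(a.size, 50.0))
            errors.append(abs(a50 - 350.0))
        assert np.median(errors) <= 10.0

    def test_degenerate_fractions_rejected(self):
        a = np.arange(200.0, 501.0, 50.0)
        with pytest.raises(FitError):
            fit_boltzmann(a, np.zeros(a.size), np.full(a.size, 50.0))

    def test_fit_is_idempotent(self):
        a = np.arange(200.0, 501.0, 25.0)
        f = boltzmann(a, 360.0, 25.0) + np.random.default_rng(1).normal(0, 0.02, a.size)
        a50, k = fit_boltzmann(a, np.clip(f, 0, 1), np.full(a.size, 40.0))
        a50b, kb = fit_boltzmann(a, boltzmann(a, a50, k), np.full(a.size, 40.0))
        assert a50b == pytest.approx(a50, abs=1e-4)
        assert kb == pytest.approx(k, abs=1e-4)


class TestIOCurve:
    def test_single_bin_for_constant_amplitude(self):
        log = make_log(amplitudes=np.full(100, 300.0),
                       y=np.random.default_rng(0).integers(0, 2, 100))
        curve = io_curve(log, (0.0, 1e6))
        assert curve.bin_centers.size == 1
        assert curve.counts[0] == 100

    def test_bins_below_minimum_count_excluded(self):
        amps = np.concatenate([np.full(9, 300.0), np.full(20, 400.0)])
        log = make_log(amplitudes=amps, y=np.ones(29, dtype=int))
        curve = io_curve(log, (0.0, 1e6))
        assert curve.bin_centers.size == 1
        assert curve.bin_centers[0] == pytest.approx(402.5)

    def test_recovers_generating_curve(self):
        rng = np.random.default_rng(3)
        amps = rng.uniform(250.0, 450.0, 6000)
        y = (rng.random(6000) < boltzmann(amps, 350.0, 20.0)).astype(int)
        curve = io_curve(make_log(amplitudes=amps, y=y), (0.0, 1e9))
        assert curve.a50 == pytest.approx(350.0, abs=15.0)
        assert (curve.fractions >= 0).all() and (curve.fractions <= 1).all()


class TestIOStability:
    @staticmethod
    def _curves_with_drift(shift_per_epoch):
        curves = []
        a = np.arange(250.0, 451.0, 5.0)
        for e in range(7):
            f = boltzmann(a, 350.0 + shift_per_epoch * e, 20.0)
            curves.append(
                IOCurve(a + 2.5, np.full(a.size, 20.0), f,
                        (e * 2400.0, (e + 1) * 2400.0))
            )
        return curves

    def test_drifting_curves_are_less_stable(self):
        static = io_stability(self._curves_with_drift(0.0))
        drifting = io_stability(self._curves_with_drift(20.0))
        assert drifting > static

    def test_no_qualifying_bins_flagged_as_nan(self):
        a = np.arange(250.0, 300.0, 5.0)
        curves = [
            IOCurve(a, np.full(a.size, 20.0), np.zeros(a.size), (0, 1)),
            IOCurve(a, np.full(a.size, 20.0), np.ones(a.size), (1, 2)),
        ]
        assert np.isnan(io_stability(curves))

    def test_needs_two_epochs(self):
        with pytest.raises(ValueError):
            io_stability(self._curves_with_drift(0.0)[:1])


class TestPairwiseCorrelations:
    def test_identical_series_correlate_perfectly(self):
        series = np.random.default_rng(0).uniform(20.0, 200.0, 50)
        elec = np.column_stack([series, series])
        df = pairwise_latency_correlations(make_log(p_tau=np.zeros(50), elec=elec))
        assert len(df) == 1
        assert df.r.iloc[0] == pytest.approx(1.0)

    def test_independent_jitter_centres_at_zero(self):
        rng = np.random.default_rng(8)
        elec = rng.uniform(20.0, 200.0, (1000, 6))
        df = pairwise_latency_correlations(make_log(p_tau=np.zeros(1000), elec=elec))
        assert len(df) == 15
        assert abs(df.r.mean()) < 0.05
        assert (df.r.abs() <= 1.0).all()

    def test_out_of_range_latencies_discarded(self):
        # electrode 1 valid on only 5 trials -> pair dropped
        elec = np.column_stack([np.full(50, 100.0), np.full(50, 500.0)])
        elec[:5, 1] = 90.0
        df = pairwise_latency_correlations(make_log(p_tau=np.zeros(50), elec=elec))
        assert len(df) == 0

    def test_dispersion_grows_with_plant_dispersion_rate(self):
        sds = []
        for rate in (0.0, 0.5, 2.0):
            log, _ = closed_loop_session(
                0.7, HOUR, seed=202, dispersion_rate=rate
            )
            sds.append(pairwise_latency_correlations(log).r.std())
        assert sds[0] < sds[1] < sds[2]


class TestSpontaneousEvokedRates:
    def test_baseline_against_itself_is_unity(self):
        base = run_no_stimulation(make_plant(5), 20_000.0)
        norm, _ = spontaneous_evoked_rates(base, base)
        assert norm == pytest.approx(1.0)

    def test_zero_baseline_flagged(self):
        base = make_log(p_tau=np.full(10, 0.5), n_spont=0)
        log = make_log(p_tau=np.full(10, 0.5), n_spont=3)
        norm, _ = spontaneous_evoked_rates(log, base)
        assert np.isnan(norm)

    def test_decoupled_plant_rate_independent_of_stimulation(self):
        base = run_no_stimulation(
            make_plant(6, suppression_gain=0.0), 4 * HOUR
        )
        log, _ = closed_loop_session(
            0.7, 4 * HOUR, seed=6, suppression_gain=0.0,
            record_electrodes=False,
        )
        norm, evoked = spontaneous_evoked_rates(log, base)
        assert evoked > 0.6
        assert norm == pytest.approx(1.0, abs=0.35)
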