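"""Plant surrogate: response curve, latency law, hidden dynamics."""

import numpy as np
import pytest

from respclamp.plant import (
    Plant,
    PlantConfig,
    PlantConfigError,
    PlantDomainError,
    boltzmann,
)

from conftest import static_config


def _stimulate(plant, amplitude, n, period=5.0):
    """Deliver n identical stimuli; return the evoked NS list."""
    t = plant.state.clock
    out = []
    for _ in range(n):
        t += period
        ns = plant.respond(amplitude, t)
        if ns is not None:
            out.append(ns)
    return out


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            {"n_electrodes": 1},
            {"a50_0": 50.0},
            {"a50_0": 950.0},
            {"k_slope": 0.0},
            {"drift_sd": -1.0},
            {"resource_depletion": 1.5},
            {"electrode_participation": 1.2},
        ],
    )
    def test_invalid_field_rejected(self, bad):
        with pytest.raises(PlantConfigError):
            PlantConfig(**bad).validate()

    def test_roundtrip_dict(self):
        cfg = static_config(a50_0=400.0)
        assert PlantConfig.from_dict(cfg.to_dict()) == cfg


class TestDeterminism:
    def test_same_seed_same_state_and_responses(self):
        a = Plant(PlantConfig(seed=7))
        b = Plant(PlantConfig(seed=7))
        np.testing.assert_array_equal(a.state.offsets, b.state.offsets)
        for t in np.arange(5.0, 500.0, 5.0):
            ra, rb = a.respond(350.0, t), b.respond(350.0, t)
            assert (ra is None) == (rb is None)
            if ra is not None:
                assert ra.latency == rb.latency
                np.testing.assert_array_equal(
                    ra.first_spike_latencies, rb.first_spike_latencies
                )
        assert a.state.a50_drift == b.state.a50_drift

    def test_different_seeds_diverge(self):
        a, b = Plant(PlantConfig(seed=1)), Plant(PlantConfig(seed=2))
        for t in np.arange(5.0, 200.0, 5.0):
            a.respond(350.0, t), b.respond(350.0, t)
        assert a.state.a50_drift != b.state.a50_drift


class TestResponseCurve:
    def test_static_plant_midpoint_is_constant(self, static_plant):
        a50 = static_plant.a50_eff
        _stimulate(static_plant, 400.0, 200)
        assert static_plant.a50_eff == a50

    def test_saturation_far_above_midpoint(self, static_plant):
        ns = _stimulate(static_plant, 900.0, 1000)
        assert len(ns) / 1000 > 0.995

    def test_midpoint_rate_matches_closed_form(self):
        # Monte-Carlo check against the Boltzmann value p = 0.5 at A = A50
        plant = Plant(static_config(seed=3))
        ns = _stimulate(plant, plant.config.a50_0, 10_000)
        assert abs(len(ns) / 10_000 - 0.5) < 0.02

    def test_probability_nondecreasing_in_amplitude(self):
        amps = [250.0, 300.0, 350.0, 400.0, 500.0]
        rates = []
        for a in amps:
            plant = Plant(static_config(seed=11))
            rates.append(len(_stimulate(plant, a, 2000)) / 2000)
        assert all(b - a > -0.03 for a, b in zip(rates, rates[1:]))
        # and each rate sits near the closed-form curve
        for a, r in zip(amps, rates):
            p = boltzmann(a, 350.0, 20.0)
            assert abs(r - p) < 3 * np.sqrt(p * (1 - p) / 2000) + 1e-3

    def test_amplitude_domain_enforced(self, static_plant):
        with pytest.raises(PlantDomainError):
            static_plant.respond(99.0, 5.0)
        with pytest.raises(PlantDomainError):
            static_plant.respond(1001.0, 10.0)


class TestLatency:
    def test_mean_latency_decreases_with_amplitude(self):
        # lower midpoint so 300 mV evokes plenty of responses
        cfg = static_config(a50_0=300.0, seed=5)
        lats = {}
        for a in (300.0, 800.0):
            plant = Plant(cfg)
            ns = _stimulate(plant, a, 1500)
            assert len(ns) >= 500
            lats[a] = np.mean([n.latency for n in ns])
        assert lats[800.0] < lats[300.0]

    def test_mean_latency_nonincreasing_over_grid(self, static_plant):
        grid = [250.0, 300.0, 350.0, 450.0, 700.0]
        means = [static_plant.mean_latency(a) for a in grid]
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))

    def test_latency_floor_respected(self):
        plant = Plant(static_config(seed=9))
        ns = _stimulate(plant, 1000.0, 500)
        assert min(n.latency for n in ns) >= PlantConfig.LATENCY_FLOOR_MS


class TestDrift:
    def test_zero_diffusion_is_static(self):
        plant = Plant(static_config())
        plant.drift_step(1000.0)
        assert plant.state.a50_drift == 0.0

    def test_stationary_sd_matches_closed_form(self):
        # OU stationary SD = drift_sd * sqrt(relaxation / 2)
        cfg = PlantConfig(seed=0)
        expected = cfg.drift_sd * np.sqrt(cfg.drift_relaxation / 2.0)
        samples = []
        for seed in range(5):
            plant = Plant(PlantConfig(seed=seed))
            for _ in range(20_000):
                plant.drift_step(5.0)
                samples.append(plant.state.a50_drift)
        sd = np.std(samples)
        assert abs(sd - expected) / expected < 0.15

    def test_distinct_seeds_distinct_paths(self):
        paths = []
        for seed in (1, 2):
            plant = Plant(PlantConfig(seed=seed))
            plant.drift_step(500.0)
            paths.append(plant.state.a50_drift)
        assert paths[0] != paths[1]


class TestPlasticity:
    def test_shift_accumulates_linearly(self):
        plant = Plant(static_config(plasticity_rate=0.05))
        for _ in range(1000):
            plant.plasticity_step(True)
        assert plant.state.plastic_shift == pytest.approx(50.0)

    def test_no_evoked_no_change(self):
        plant = Plant(static_config(plasticity_rate=0.05, dispersion_rate=1.0))
        before = plant.state.offsets.copy()
        for _ in range(100):
            plant.plasticity_step(False)
        assert plant.state.plastic_shift == 0.0
        np.testing.assert_array_equal(plant.state.offsets, before)

    def test_offset_dispersion_grows_like_sqrt_n(self):
        # random-walk law: SD across electrodes after N steps ~ rate * sqrt(N)
        cfg = static_config(dispersion_rate=1.0, offset_sd=0.0,
                            n_electrodes=60, seed=21)
        plant = Plant(cfg)
        sds, steps = {}, 0
        for n_target in (100, 400):
            while steps < n_target:
                plant.plasticity_step(True)
                steps += 1
            sds[n_target] = plant.state.offsets.std()
        assert sds[400] / sds[100] == pytest.approx(2.0, rel=0.35)
        assert sds[100] == pytest.approx(10.0, rel=0.35)

    def test_shift_monotone_and_resource_bounded(self):
        plant = Plant(PlantConfig(seed=13))
        rng = np.random.default_rng(0)
        last_shift, t = 0.0, 0.0
        for _ in range(500):
            t += rng.uniform(1.0, 10.0)
            plant.respond(rng.uniform(100.0, 1000.0), t)
            assert plant.state.plastic_shift >= last_shift
            assert 0.0 <= plant.state.resource <= 1.0
            last_shift = plant.state.plastic_shift


class TestSpontaneous:
    def test_unsuppressed_rate_matches_config(self):
        plant = Plant(static_config(seed=2))
        events = plant.spontaneous(0.0, 50_000.0)
        rate = len(events) / 50_000.0
        assert rate == pytest.approx(plant.config.spont_rate_0, rel=0.15)

    def test_evoked_activity_suppresses_rate(self):
        plant = Plant(static_config(seed=4))
        _stimulate(plant, 600.0, 200)  # drive evoked activity hard
        assert plant.spontaneous_rate() < plant.config.spont_rate_0 * 0.5

    def test_zero_gain_decouples(self):
        plant = Plant(static_config(suppression_gain=0.0, seed=4))
        _stimulate(plant, 600.0, 200)
        assert plant.spontaneous_rate() == plant.config.spont_rate_0
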