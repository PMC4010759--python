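import numpy as np
import pytest

from respclamp.plant import Plant, PlantConfig


def static_config(**overrides) -> PlantConfig:
    """Plant with every slow process frozen: pure Boltzmann responder."""
    base = dict(
        drift_sd=0.0,
        latency_drift_sd=0.0,
        plasticity_rate=0.0,
        dispersion_rate=0.0,
        resource_depletion=0.0,
        seed=0,
    )
    base.update(overrides)
    return PlantConfig(**base)


@pytest.fixture
def static_plant() -> Plant:
    return Plant(static_config())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
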