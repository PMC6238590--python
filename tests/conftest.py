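import pytest

from adipoflux import (
    CultureGeometry,
    ModelConstants,
    default_truth,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def geometry():
    return CultureGeometry()


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Synthetic experiment at published condition means, zero noise."""
    truth = default_truth(seed=7).noise_free()
    return simulate_experiment(truth)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Synthetic experiment with the default 10% well noise, 6 wells."""
    truth = default_truth(seed=42)
    return simulate_experiment(truth)
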