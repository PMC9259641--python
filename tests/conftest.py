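import numpy as np
import pytest

from weakseg import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def sparse_config():
    """Small fields with a handful of well-separated vesicles."""
    return SimulationConfig(
        width=96,
        height=96,
        n_images=6,
        seed=11,
        phagophore_count_mean=6,
        autolysosome_count_mean=3,
    )


@pytest.fixture(scope="session")
def sparse_samples(sparse_config):
    return generate_dataset(sparse_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """Noise- and clutter-free fields for exact pipeline checks."""
    return SimulationConfig(
        width=96,
        height=96,
        n_images=4,
        seed=21,
        phagophore_count_mean=4,
        autolysosome_count_mean=2,
        noise_gaussian_sd=0.0,
        noise_poisson_scale=0.0,
        clutter_density=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_samples(noiseless_config):
    return generate_dataset(noiseless_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
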