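import numpy as np
import pytest

from hypyield.containers import SampleTable
from hypyield.synthetic import SceneConfig, generate_samples


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A modest noiseless scene reused across model tests."""
    return SceneConfig(n_samples=150, n_bands=32, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_table(small_config) -> SampleTable:
    table, _ = generate_samples(small_config)
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
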