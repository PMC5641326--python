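import numpy as np
import pytest

from canopyx.pipeline import compute_index_table
from canopyx.synthetic import SyntheticConfig, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One full 90-plot synthetic trial under the default study conditions."""
    return generate_trial(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def index_table(default_trial):
    """The merged per-plot index table for the default trial."""
    return compute_index_table(default_trial)


@pytest.fixture(scope="session")
def exact_config():
    """Jitter-free, noise-free generator config for exact-recovery oracles."""
    return SyntheticConfig(
        seed=5,
        hue_jitter=0.0,
        hue_shift_sd=0.0,
        saturation_jitter=0.0,
        value_jitter=0.0,
        band_noise_sd=0.0,
        thermal_noise_sd=0.0,
        yield_noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
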