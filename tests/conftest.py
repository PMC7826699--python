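import numpy as np
import pytest
from hypothesis import settings

from olce import SimConfig, generate_dataset, zero_center_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """3 classes x 8 samples of the default sensor geometry."""
    return generate_dataset(SimConfig(n_classes=3, n_per_class=8, seed=11))


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    return zero_center_dataset(small_dataset)


@pytest.fixture(scope="session")
def toy2_normalized():
    """Noiseless 2-class toy set of 10 samples (memorization target)."""
    cfg = SimConfig(n_classes=2, n_per_class=5, noise_sd=0.0, gain_sd=0.0, seed=3)
    return zero_center_dataset(generate_dataset(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
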