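import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msffnet as mf

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_params():
    return mf.PhantomParams(volume_shape=(32, 32, 16))


@pytest.fixture(scope="session")
def phantom_case(phantom_params):
    return mf.generate_case(phantom_params, seed=42)


@pytest.fixture(scope="session")
def phantom_cohort(phantom_params):
    return mf.generate_cohort(6, phantom_params, seed=7)


@pytest.fixture
def random_probs(rng):
    """Random valid (8, 8, 5) probability map + matching one-hot labels."""
    raw = rng.random((8, 8, 5)) + 1e-3
    P = raw / raw.sum(-1, keepdims=True)
    G = mf.one_hot(rng.integers(0, 5, (8, 8)))
    return P, G


@pytest.fixture(scope="session")
def tiny_net_config():
    """Smallest architecture that exercises every branch of the model."""
    return mf.NetConfig(
        input_size=16,
        stage_channels=(4, 6, 8, 10, 12),
        fusing_channels=8,
        dropout_rate=0.0,
        seed=1,
    )
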