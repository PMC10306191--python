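import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rsvpsim as rs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down synthetic world for fast tests (structure unchanged)."""
    return rs.SynthConfig(
        n_categories=24,
        n_exemplars=8,
        image_shape=(1, 6, 6),
        n_trials=40,
        n_subjects=10,
        prototype_k=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bank(small_config):
    return rs.generate_image_bank(small_config)


@pytest.fixture(scope="session")
def toy_net(small_bank):
    return rs.build_toy_classifier(small_bank, hidden_units=24, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
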