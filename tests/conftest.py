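import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Low-noise single-tumor phantom spec used across modules."""
    from uatransnet.phantom import PhantomSpec
    return PhantomSpec(seed=3, noise_sd=0.02, edge_blur_sigma=1.0)
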