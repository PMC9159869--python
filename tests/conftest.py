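import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """128x128 phantom in the noiseless limit, with its ground truth."""
    import math

    from ovaseg import PhantomConfig, make_phantom

    cfg = PhantomConfig(seed=11, speckle_looks=math.inf, blur_sigma=0.0)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def speckled_phantom():
    """Speckled 128x128 phantom (4-look), with its ground truth."""
    from ovaseg import PhantomConfig, make_phantom

    return make_phantom(PhantomConfig(seed=7))
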