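import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def std_normal_1d():
    from movetarget import Normal1D, ProductTarget
    return ProductTarget([Normal1D()])


@pytest.fixture
def std_normal_2d():
    from movetarget import Normal1D, ProductTarget
    return ProductTarget([Normal1D(), Normal1D()])


@pytest.fixture
def bimodal_2d():
    """x: logistic mixture (locations +-1, scale 1, weights 0.6/0.4); y: logistic."""
    from movetarget import Logistic1D, LogisticMixture1D, ProductTarget
    return ProductTarget([
        LogisticMixture1D([-1.0, 1.0], [1.0, 1.0], [0.6, 0.4]),
        Logistic1D(0.0, 1.0),
    ])
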