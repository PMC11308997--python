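import numpy as np
import pytest

from pterolaunch.synthetic import make_hinge_toy, make_pulley_toy, make_quadruped_toy


@pytest.fixture(scope="session")
def hinge():
    """Single z-axis hinge with one straight MTU and its analytic MA(q)."""
    model, analytic = make_hinge_toy()
    return model, analytic


@pytest.fixture(scope="session")
def pulley():
    model, interval = make_pulley_toy(radius=0.05)
    return model, interval


@pytest.fixture(scope="session")
def quadruped():
    """The packaged reference model plus its three take-off sequences."""
    return make_quadruped_toy(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
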