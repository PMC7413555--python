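import numpy as np
import pytest

from viscocurve import make_history, make_probe


@pytest.fixture(scope="session")
def sphere():
    return make_probe("sphere", 5e-6)


@pytest.fixture(scope="session")
def cylinder():
    return make_probe("cylinder", 0.4e-6)


@pytest.fixture(scope="session")
def cone():
    return make_probe("cone", np.deg2rad(85.0))


@pytest.fixture(scope="session")
def tri_ramp():
    """Default triangular ramp: 100 nm depth, t_m = 50 ms."""
    return make_history("triangular", 100e-9, 0.05)


@pytest.fixture(scope="session")
def sin_ramp():
    return make_history("sinusoidal", 100e-9, 0.05)
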