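import numpy as np
import pytest

from amide2d import default_axes, make_component_library


@pytest.fixture(scope="session")
def axes():
    return default_axes()


@pytest.fixture(scope="session")
def pump_axis(axes):
    return axes[0]


@pytest.fixture(scope="session")
def probe_axis(axes):
    return axes[1]


@pytest.fixture(scope="session")
def ffpe_library():
    return make_component_library("ffpe")


@pytest.fixture(scope="session")
def frozen_library():
    return make_component_library("frozen")


def rotated_gauss(P, B, cx, cy, sd, sa):
    """Independent re-statement of the rotated-Gaussian lineshape (oracle)."""
    d = ((P - cx) + (B - cy)) / 2.0
    a = ((B - cy) - (P - cx)) / 2.0
    return np.exp(-(d**2) / (2 * sd**2) - (a**2) / (2 * sa**2))
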