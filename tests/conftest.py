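import numpy as np
import pytest

from optoscreen.photometry import AngularProfile
from optoscreen.presets import action_spectrum, honor8_display


@pytest.fixture(scope="session")
def honor8():
    return honor8_display()


@pytest.fixture(scope="session")
def lambertian():
    return AngularProfile.lambertian()


@pytest.fixture(scope="session")
def cschrimson():
    return action_spectrum("cschrimson")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
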