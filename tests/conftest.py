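import numpy as np
import pytest

from hyse import default_chart, make_reference_library

# A reduced wavelength grid keeps unit tests fast; 242 bins twice into 121.
UNIT_N_WL = 242


@pytest.fixture(scope="session")
def library():
    return make_reference_library(seed=0, n_wavelengths=UNIT_N_WL)


@pytest.fixture(scope="session")
def chart():
    return default_chart()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
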