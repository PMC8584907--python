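import numpy as np
import pytest

from thzhyd import FrequencyGrid, eval_model
from thzhyd.model import PURE_WATER


@pytest.fixture(scope="session")
def grid():
    """Default 250-point 10-110 cm^-1 analysis grid."""
    return FrequencyGrid.default()


@pytest.fixture(scope="session")
def water_spectrum(grid):
    """Noiseless model permittivity of pure water on the default grid."""
    return eval_model(PURE_WATER, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
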