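import numpy as np
import pytest

from crumbsim.constitutive import MaterialParams
from crumbsim.fields import initialize, make_grid


@pytest.fixture(scope="session")
def params():
    return MaterialParams()


@pytest.fixture()
def column_setup(params):
    """Small 1-D column with the default initial state."""
    grid = make_grid(radius=0.05, height=0.020, nz=10, mode="axial1d")
    state = initialize(grid, params)
    return state, grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250923)
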