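import numpy as np
import pytest

from halftone_sfdi import TransportConfig, simulate_white_mc
from halftone_sfdi.lut import build_lut, default_grids


@pytest.fixture(scope="session")
def mc_table():
    """Moderate-size white MC photon table shared by the unit tests."""
    return simulate_white_mc(TransportConfig(n_photons=150_000, seed=1234))


@pytest.fixture(scope="session")
def small_lut(mc_table):
    """40x40 LUT over the default padded grids at (0, 0.1) /mm."""
    mua_grid, musp_grid = default_grids(40, 40)
    return build_lut(mc_table, mua_grid, musp_grid, (0.0, 0.1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
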