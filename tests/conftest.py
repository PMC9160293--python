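"""Shared fixtures: parameter sets and calibrated maps at two scales."""

import numpy as np
import pytest

from aedesgm.equilibrium import calibrate_carrying_capacities
from aedesgm.maps import reference_city_map, synthesize_city_map, with_capacities
from aedesgm.parameters import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def reference_grid(params):
    """The committed 40×40 city map, capacities calibrated to 10000 females."""
    grid = reference_city_map()
    K_h, K_s = calibrate_carrying_capacities(params, grid, 10000.0)
    return with_capacities(grid, K_h, K_s)


@pytest.fixture(scope="session")
def small_grid(params):
    """A fast 10×10 city map calibrated to a 600-female equilibrium."""
    grid = synthesize_city_map(10, 10, street_period=4, street_width=1, seed=3)
    K_h, K_s = calibrate_carrying_capacities(params, grid, 600.0)
    return with_capacities(grid, K_h, K_s)


@pytest.fixture(scope="session")
def small_footprint(small_grid):
    """Central 4-cell release footprint for the small map."""
    mask = np.zeros((small_grid.ny, small_grid.nx), dtype=bool)
    mask[4:6, 4:6] = True
    return mask
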