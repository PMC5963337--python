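import numpy as np
import pytest

from demogrid import Grid, ScenarioConfig, make_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default 3-country synthetic world (urban/rural ASFR, registered
    births, crude-birth-rate countries)."""
    return make_scenario(ScenarioConfig(seed=0))


@pytest.fixture
def small_grid():
    """A 4x6 float grid with two masked cells on the master lattice."""
    values = np.arange(24, dtype=np.float64).reshape(4, 6)
    mask = np.zeros((4, 6), dtype=bool)
    mask[0, 0] = mask[3, 5] = True
    return Grid(values=values, mask=mask, origin=(-10.0, 5.0))


def make_uniform_grid(shape, value, origin=(-10.0, 5.0), mask=None):
    values = np.full(shape, float(value))
    if mask is None:
        mask = np.zeros(shape, dtype=bool)
    return Grid(values=values, mask=mask, origin=origin)
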