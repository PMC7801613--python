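import numpy as np
import pytest

from angiosim.fields import Grid, ScalarField


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid7():
    """Small cubic grid with unit spacing and unit time step."""
    return Grid(points_per_axis=7, domain_edge=7.0, dt=1.0)


@pytest.fixture
def grid9():
    return Grid(points_per_axis=9, domain_edge=9.0, dt=1.0)


def make_field(grid, values=None, boundary=0.0, name="f"):
    if values is None:
        values = np.zeros(grid.shape)
    return ScalarField(name, np.asarray(values, dtype=float), boundary)
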