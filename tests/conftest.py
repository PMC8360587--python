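import pandas as pd
import pytest

import ssii
from ssii.grid import grid_occurrences


@pytest.fixture(scope="session")
def fig1():
    """The two-species worked-example world."""
    return ssii.fig1_fixture()


@pytest.fixture(scope="session")
def fig1_gridded(fig1):
    gridded, rejections = grid_occurrences(fig1.occurrences, fig1.grid)
    assert sum(rejections.values()) == 0
    return gridded


@pytest.fixture(scope="session")
def fig1_species_indices(fig1, fig1_gridded):
    return ssii.species_indices_table(
        fig1.ranges, fig1.countries, fig1_gridded, [2019])


@pytest.fixture(scope="session")
def small_world():
    """A modest random world reused by aggregation and pipeline tests."""
    return ssii.make_world(ssii.WorldConfig(
        n_cols=10, n_rows=6, n_countries=3,
        n_species={"birds": 6, "mammals": 4},
        range_size=(3, 12), lam=20.0, theta=0.5,
        years=tuple(range(2010, 2020)), seed=42))
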