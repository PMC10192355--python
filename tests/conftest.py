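"""Shared fixtures: desk-scale cities and their navigation fields.

Session-scoped because city generation and the multi-source Dijkstra
field are by far the most expensive fixtures; every test works on the
same frozen models (seed 1, 500 m extent).
"""

import numpy as np
import pytest

from evacsim import CityParams, generate_city
from evacsim.navigation import navigation_field_for


@pytest.fixture(scope="session")
def grid_city():
    return generate_city(CityParams(style="grid", extent=500.0, seed=1))


@pytest.fixture(scope="session")
def root_city():
    return generate_city(CityParams(style="root", extent=500.0, seed=1))


@pytest.fixture(scope="session")
def grid_nav(grid_city):
    return navigation_field_for(grid_city)


@pytest.fixture(scope="session")
def root_nav(root_city):
    return navigation_field_for(root_city)


@pytest.fixture(scope="session")
def small_city():
    """A compact grid town for fast engine tests."""
    return generate_city(
        CityParams(style="grid", extent=150.0, street_spacing=50.0, seed=3)
    )


@pytest.fixture(scope="session")
def small_nav(small_city):
    return navigation_field_for(small_city)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
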