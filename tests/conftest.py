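import datetime as dt

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from bacips import (
    FireEvent,
    Location,
    SamplerConfig,
    StudyMonths,
    default_study_config,
    simulate_scenario,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def two_fires():
    """Two square fires: 'west' (2016-07-28) and 'east' (2017-07-11), with a
    small overlap strip at x in [900, 1000]."""
    west = FireEvent("west", dt.date(2016, 7, 28), box(0.0, 0.0, 1000.0, 1000.0))
    east = FireEvent("east", dt.date(2017, 7, 11), box(900.0, 0.0, 2000.0, 1000.0))
    return [west, east]


@pytest.fixture(scope="session")
def study_months():
    return StudyMonths(2008, 1, 144)


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced study-scale scenario for fast end-to-end tests."""
    cfg = default_study_config(seed=42)
    cfg.n_birds = 60
    return cfg, simulate_scenario(cfg)


@pytest.fixture(scope="session")
def default_scenario():
    cfg = default_study_config(seed=7)
    return cfg, simulate_scenario(cfg)


@pytest.fixture
def quick_sampler():
    return SamplerConfig(n_chains=2, n_iterations=1200, burn_in=400, thin=2, seed=9)


def make_location(x, y, date=dt.date(2015, 5, 1), bird="b1", status="alive"):
    return Location(bird_id=bird, date=date, x=x, y=y, status=status)


@pytest.fixture(scope="session")
def concave_decagon(rng):
    """A random concave (simple) decagon for point-in-polygon oracle tests."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, 10))
    radii = rng.uniform(0.4, 1.6, 10)  # uneven radii make it concave
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    poly = Polygon(pts)
    assert poly.is_valid
    return poly
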