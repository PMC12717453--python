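import numpy as np
import pytest

from stoatsim.config import SimConfig
from stoatsim.geometry import IslandGeometry, make_synthetic_island
from shapely.geometry import Polygon


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def square_island():
    """A 2 km x 2 km (4 km²) square island, exactly known geometry."""
    return IslandGeometry(Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)]))


@pytest.fixture(scope="session")
def small_island():
    """A ~4 km² synthetic island used for fast end-to-end runs."""
    return make_synthetic_island(4.0, 1.5, seed=3)


@pytest.fixture(scope="session")
def study_island():
    """The 208 km² synthetic stand-in for the study island."""
    return make_synthetic_island(208.0, 2.5, seed=7)


@pytest.fixture
def base_config():
    return SimConfig()
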