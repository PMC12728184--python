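import numpy as np
import pytest

from treedsim.optimiser import CellClimate
from treedsim.params import PhysiologyParams, WeatheringParams


MONTH_PHASE = np.cos(2.0 * np.pi * (np.arange(12) - 6.0) / 12.0)


def make_climate(t_mean, t_amp, p_mean, rsds_mean, rsds_amp=0.0, lat=40.0,
                 p_season=0.0):
    """Seasonal cell climate with a mid-year temperature peak."""
    t = t_mean + t_amp * MONTH_PHASE
    p = np.maximum(p_mean * (1.0 + p_season * MONTH_PHASE), 0.0)
    r = np.maximum(rsds_mean + rsds_amp * MONTH_PHASE, 0.0)
    return CellClimate(t, p, r, lat)


def random_climate(rng):
    """A random but physically plausible cell climate."""
    lat = rng.uniform(-70.0, 70.0)
    t_mean = 28.0 - 33.0 * np.sin(np.deg2rad(lat)) ** 2 + rng.normal(0, 2)
    t_amp = (2.0 + 15.0 * abs(np.sin(np.deg2rad(lat)))) * rng.uniform(0.6, 1.2)
    p_mean = rng.uniform(20.0, 250.0)
    rsds = max(80.0, 260.0 * np.cos(np.deg2rad(lat)) * rng.uniform(0.8, 1.1))
    return make_climate(t_mean, t_amp * np.sign(lat) if lat < 0 else t_amp,
                        p_mean, rsds, rsds_amp=0.3 * rsds * np.sign(lat),
                        lat=lat)


@pytest.fixture(scope="session")
def phys():
    return PhysiologyParams()


@pytest.fixture(scope="session")
def weath():
    return WeatheringParams()


@pytest.fixture(scope="session")
def tropical_climate():
    return make_climate(26.0, 1.0, 200.0, 220.0, lat=5.0)


@pytest.fixture(scope="session")
def temperate_climate():
    return make_climate(12.0, 9.0, 90.0, 180.0, rsds_amp=90.0, lat=40.0)


@pytest.fixture(scope="session")
def boreal_climate():
    return make_climate(2.0, 14.0, 60.0, 150.0, rsds_amp=110.0, lat=55.0)
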