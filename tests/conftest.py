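import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import whaletrack as wt

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def env():
    return wt.Environment()


@pytest.fixture(scope="session")
def array_pair():
    """Two tetrahedral arrays 1 km apart, 6 m above a 1300 m seafloor."""
    return wt.default_array_pair(separation=1000.0, seafloor_depth=1300.0)


@pytest.fixture(scope="session")
def tetra(array_pair):
    return array_pair[0]


@pytest.fixture(scope="session")
def flat_bathy():
    return wt.generate_bathymetry("flat", {"depth": 1300.0}, (8000.0, 8000.0), 100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def straight_track(start, velocity, n, dt=1.0, whale_id="w"):
    """Constant-velocity Track helper used across test modules."""
    t = np.arange(n) * dt
    pos = np.asarray(start, float)[None, :] + t[:, None] * np.asarray(velocity, float)[None, :]
    return wt.Track(whale_id=whale_id, times=t, positions=pos,
                    smoothed_positions=pos.copy())
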