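import numpy as np
import pytest

import gridhex as gx


@pytest.fixture(scope="session")
def small_population():
    """64 uniform-phase cells with default grid parameters."""
    return gx.GridPopulation(phases=gx.sample_phases(64, seed=101))


@pytest.fixture(scope="session")
def tiny_population():
    return gx.GridPopulation(phases=gx.sample_phases(8, seed=7))


@pytest.fixture(scope="session")
def small_star():
    """Coarse star-like walk: 60 directions, 60 cm segments."""
    return gx.star_walk(n_angles=60, r_max=60.0, v=10.0, dt=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
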