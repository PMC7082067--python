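import numpy as np
import pytest

from imtracer.timegrid import make_time_grid


@pytest.fixture(scope="session")
def analysis_grid():
    """The default two-population analysis grid (28 parameter segments,
    grid time scale 20,000 generations)."""
    return make_time_grid(n_ref=10_000)


@pytest.fixture(scope="session")
def coarse_grid():
    """A small identity-pattern grid for cheap model checks."""
    return make_time_grid("8*1", n_ref=10_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
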