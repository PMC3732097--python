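import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nichecast.grids import EnvStack, OccurrenceSet, SWDTable

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_stack():
    """A 10x10 two-layer stack over (0..10E, 0..10N) with a 3-cell island."""
    rng = np.random.default_rng(42)
    a = rng.uniform(0, 10, (10, 10))
    b = rng.uniform(20, 30, (10, 10))
    valid = np.ones((10, 10), dtype=bool)
    valid[4, 4] = valid[4, 5] = valid[5, 4] = False
    return EnvStack(["alpha", "beta"], np.stack([a, b]),
                    (0.0, 10.0, 0.0, 10.0), 1.0, valid)


@pytest.fixture
def ocean_stack():
    """An all-ocean 20x20 single-layer stack spanning 0..60N."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(0, 1, (20, 20))
    return EnvStack(["depth"], vals[None], (0.0, 60.0, 0.0, 60.0), 3.0,
                    np.ones((20, 20), dtype=bool))


@pytest.fixture
def occurrences(small_stack):
    lons = [0.5, 2.5, 2.6, 7.5, 9.5]
    lats = [0.5, 3.5, 3.6, 7.5, 9.5]
    return OccurrenceSet.from_points(lons, lats, region="native")


def make_swd(values, species="sp", name="x"):
    """1-predictor SWD table from raw values (coordinates are dummies)."""
    values = np.asarray(values, dtype=float)
    return SWDTable(pd.DataFrame({
        "species": species,
        "longitude": np.linspace(-10, 10, values.size),
        "latitude": np.zeros(values.size),
        name: values,
    }))
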