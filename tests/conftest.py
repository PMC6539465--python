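import numpy as np
import pandas as pd
import pytest

from iltox.surfaces import SurfaceSegmentSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_surface(rng):
    """A 500-segment surface with σ spread across the whole grid."""
    n = 500
    areas = rng.uniform(0.05, 2.0, n)
    sigmas = rng.uniform(-0.03, 0.03, n)
    return SurfaceSegmentSet(ion_id="ionX", areas=areas, sigmas=sigmas)


@pytest.fixture
def small_linear_table(rng):
    """20 samples, 3 exactly-linear descriptors, no noise."""
    X = rng.normal(size=(20, 3))
    coefs = np.array([1.5, -2.0, 0.75])
    y = 0.4 + X @ coefs
    table = pd.DataFrame(X, columns=["d1", "d2", "d3"])
    table["logEC50"] = y
    return table, 0.4, coefs
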