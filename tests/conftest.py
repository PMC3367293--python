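import numpy as np
import pytest

from morankrig import SampleSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_samples(coords, values=None, analyte="metal"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if values is None:
        values = np.arange(1.0, n + 1.0)
    return SampleSet(
        sample_id=[f"s{i}" for i in range(n)],
        x=coords[:, 0],
        y=coords[:, 1],
        values={analyte: np.asarray(values, dtype=float)},
    )


@pytest.fixture
def random_samples(rng):
    """20 scattered points with lognormal concentrations."""
    coords = rng.uniform(0, 50, size=(20, 2))
    vals = np.exp(rng.normal(4.0, 0.5, size=20))
    return make_samples(coords, vals)


@pytest.fixture
def transect_samples():
    """Six collinear points, unit spacing, linearly increasing values."""
    return make_samples([(float(i), 0.0) for i in range(6)], np.arange(1.0, 7.0))
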