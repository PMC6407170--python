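import numpy as np
import pytest

from gpsurface import MarkerMatrix, PhenotypeVector


def make_matrix(dosages, truth=None):
    """MarkerMatrix from a plain nested list / array (NaN = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    return MarkerMatrix(
        line_ids=[f"L{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(p)],
        dosages=dosages,
        truth=truth,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_panel(rng):
    """20 lines x 50 markers with scattered missing calls."""
    dosages = rng.integers(0, 3, size=(20, 50)).astype(float)
    miss = rng.random((20, 50)) < 0.15
    truth = dosages.copy()
    dosages[miss] = np.nan
    return make_matrix(dosages, truth=truth)


@pytest.fixture
def small_phenotype(rng):
    vals = rng.standard_normal(20)
    return PhenotypeVector(line_ids=[f"L{i}" for i in range(20)], values=vals)
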