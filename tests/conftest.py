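import numpy as np
import pytest

from infilstat import PointPattern, RadiusGrid, Window


@pytest.fixture
def window():
    return Window()


@pytest.fixture
def csr_pattern(window):
    """A 500-point uniform (CSR) pattern in the default window."""
    rng = np.random.default_rng(12345)
    return PointPattern(rng.uniform(0, 1.5, size=(500, 2)), window)


@pytest.fixture
def small_grid():
    return RadiusGrid(dr=0.05, r_max=0.5)


def random_pattern(n, seed, window=None):
    window = window or Window()
    rng = np.random.default_rng(seed)
    xy = rng.uniform([0, 0], [window.width, window.height], size=(n, 2))
    return PointPattern(xy, window)
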