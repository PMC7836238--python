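import numpy as np
import pytest

from confsets import DomainGrid, SubjectStack


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_grid():
    return DomainGrid((8, 8))


@pytest.fixture
def gaussian_stack(rng, small_grid):
    """N=20 i.i.d. N(0.5, 1) fields on an 8x8 grid (no spatial smoothing)."""
    data = rng.standard_normal((20, 8, 8)) + 0.5
    return SubjectStack(small_grid, data)
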