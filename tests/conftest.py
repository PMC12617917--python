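import numpy as np
import pytest

from rhythmdesign import Design, equispaced_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_design(rng):
    """A 10-point uniform-random design (sorted, distinct)."""
    while True:
        t = np.sort(rng.random(10))
        if np.all(np.diff(t) > 1e-6):
            return Design(t)


@pytest.fixture
def equi8():
    return equispaced_design(8)
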