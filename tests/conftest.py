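import logging

import numpy as np
import pytest

from codaf import CompositionSeries, closure

# repair/clamp warnings are expected throughout; keep test output readable
logging.getLogger("codaf").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20190411)


@pytest.fixture
def random_composition(rng):
    """Factory for strictly positive random compositions of dimension D."""

    def make(D=3, alpha=2.0):
        return closure(rng.dirichlet(np.full(D, alpha)) + 1e-9)

    return make


@pytest.fixture
def constant_series():
    """30 years of an unchanging composition."""
    return CompositionSeries.from_matrix(
        range(1990, 2020), np.tile([0.2, 0.5, 0.3], (30, 1)), ("young", "middle", "old")
    )
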