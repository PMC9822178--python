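import hypothesis
import numpy as np
import pytest

from sentifuse.corpus import LABEL_ORDER

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def random_bba(rng, n_focal=7):
    """Random BBA: Dirichlet mass over the 7 nonempty subsets."""
    m = np.zeros(8)
    m[1:] = rng.dirichlet(np.ones(7))
    return m


def random_singleton_bba(rng):
    m = np.zeros(8)
    m[[1, 2, 4]] = rng.dirichlet(np.ones(3))
    return m


@pytest.fixture
def labels():
    return LABEL_ORDER
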