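import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def laplace_mixture():
    """4 super-Gaussian sources through a random square mixing matrix."""
    r = np.random.default_rng(7)
    sources = r.laplace(size=(4, 20000))
    mixing = r.normal(size=(4, 4))
    return mixing @ sources, mixing, sources
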