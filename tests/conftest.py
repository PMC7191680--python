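import numpy as np
import pytest

from clinsts import SyntheticConfig, generate_pairs
from clinsts.models import FeatureContext
from clinsts.semantic import HashProjectionEmbedder


@pytest.fixture(scope="session")
def backend():
    return HashProjectionEmbedder()


@pytest.fixture(scope="session")
def small_pairs():
    """A small labeled synthetic dataset shared by fast model tests."""
    return generate_pairs(SyntheticConfig(n_pairs=60, seed=11))


@pytest.fixture(scope="session")
def small_ctx(small_pairs):
    ctx = FeatureContext()
    ctx.fit_idf(small_pairs)
    return ctx


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
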