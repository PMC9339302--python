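import numpy as np
import pytest

from poolseg import build_genome
from poolseg.datasets import revertant_pool_tables


@pytest.fixture(scope="session")
def small_genome():
    """A 4-chromosome, 20-gene genome reused across simulation tests."""
    return build_genome(4, 5, 300, seed=11)


@pytest.fixture(scope="session")
def pool_tables():
    """The bundled revertant pool A/B frequency tables."""
    return revertant_pool_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
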