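import numpy as np
import pytest

from plastevo.cppn import make_initial_genotype


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_genotypes(rng):
    """A batch of random initial genotypes, one per plasticity mode."""

    def factory(mode, n=5):
        return [make_initial_genotype(rng, mode) for _ in range(n)]

    return factory
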