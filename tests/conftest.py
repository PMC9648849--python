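import numpy as np
import pytest

from invwalk import Genome
from invwalk.fixtures import fixture_genomes, fixture_landscapes


@pytest.fixture
def standard_genomes():
    """The N=4 corner cases: uniform genomes and the alternating genome."""
    return fixture_genomes()


@pytest.fixture
def small_landscapes():
    """Seeded N=6 landscapes at K=0 and K=2 (adjacent neighbourhood)."""
    return fixture_landscapes()


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_genome(rng, N, topology="circular"):
    return Genome.from_array(rng.integers(0, 2, size=N, dtype=np.uint8), topology)
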