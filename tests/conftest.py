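import numpy as np
import pytest

from fishkit import fixtures
from fishkit.genome import GenomeSequence


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    return fixtures.synth_genome({"chr1": 8_000, "chr2": 4_000}, seed=11)


@pytest.fixture(scope="session")
def uniform_db(small_genome):
    """Oligos every 60 bp (k=40, gap=20): perfectly even spacing."""
    return fixtures.synth_database(small_genome, k=40, gap=20, seed=0)


@pytest.fixture(scope="session")
def jittered_db(small_genome):
    return fixtures.synth_database(small_genome, k=40, gap=("gamma", 30, 3), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
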