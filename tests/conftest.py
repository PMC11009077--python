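import numpy as np
import pytest

from rohkin import load_genetic_map
from rohkin.consang import build_null
from rohkin.pedigree import UnionType


@pytest.fixture(scope="session")
def genome():
    return load_genetic_map("default")


@pytest.fixture(scope="session")
def one_chrom_genome():
    from rohkin.genome import ChromosomeMap, GenomeMap

    return GenomeMap((ChromosomeMap("1", 286.28),))


@pytest.fixture(scope="session")
def fc_null_small(genome):
    """First-cousin null at modest size for unit-level checks."""
    return build_null(UnionType.FIRST_COUSIN, genome, n_reps=1500, seed=11)


@pytest.fixture(scope="session")
def fc_null_10k(genome):
    """First-cousin null at the size used for the published percentiles."""
    return build_null(UnionType.FIRST_COUSIN, genome, n_reps=10_000, seed=1)


@pytest.fixture(scope="session")
def sc_null_10k(genome):
    return build_null(UnionType.SECOND_COUSIN, genome, n_reps=10_000, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
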