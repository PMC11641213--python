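import numpy as np
import pytest

from ssrpg.matrix import GenotypeMatrix


def make_matrix(calls, pops=None, ids=None, loci=None) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a nested call list.

    ``calls[i][j]`` is a 2-tuple of allele codes (0,0 = missing).
    """
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[0], calls.shape[1]
    ids = ids if ids is not None else [f"A{i + 1}" for i in range(n)]
    pops = pops if pops is not None else ["pop1"] * n
    loci = loci if loci is not None else [f"L{j + 1}" for j in range(L)]
    return GenotypeMatrix(ids, pops, loci, calls)


@pytest.fixture(scope="session")
def study_like():
    from ssrpg.synthetic_data import study_like_dataset

    return study_like_dataset(seed=1)


@pytest.fixture
def two_pop_fixed():
    """Two populations each fixed for a different allele at one locus."""
    return make_matrix(
        [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]],
        pops=["p1", "p1", "p2", "p2"],
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    """Two well-separated populations for admixture recovery tests."""
    from ssrpg.synthetic_data import SimParams, simulate_dataset

    params = SimParams(
        pop_sizes=(50, 50), alleles_per_locus=(2,) * 20,
        fst_target=0.3, seed=7,
    )
    return simulate_dataset(params)
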