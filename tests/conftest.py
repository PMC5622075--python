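import numpy as np
import pytest

from grwlda import (
    AssociationDataset,
    GrwParams,
    SynthConfig,
    all_disease_similarities,
    build_dags,
    generate,
)


@pytest.fixture(scope="session")
def small_bench():
    """A small planted-block benchmark: 12 lncRNAs x 16 diseases, 2 blocks."""
    return generate(SynthConfig(n_lncrna=12, n_disease=16, n_blocks=2,
                                tree_depth=4, assoc_per_block=12,
                                noise_assoc=3, seed=7))


@pytest.fixture(scope="session")
def small_dd(small_bench):
    ds = small_bench.dataset
    dags = build_dags(small_bench.tree_numbers, 0.5, order=ds.disease_ids)
    return all_disease_similarities([dags[d] for d in ds.disease_ids])


@pytest.fixture
def toy_dataset():
    """3 lncRNAs x 3 diseases with a hand-placed association pattern."""
    AS = np.array([[1, 1, 0],
                   [0, 1, 0],
                   [0, 0, 1]], dtype=np.int8)
    return AssociationDataset(["L1", "L2", "L3"], ["D1", "D2", "D3"], AS)


@pytest.fixture
def fast_params():
    return GrwParams(tol=1e-10, max_iter=5000)


def random_stochastic(rng, n, density=1.0):
    """Random column-stochastic matrix (zero columns allowed at density<1)."""
    M = rng.random((n, n))
    if density < 1.0:
        M *= rng.random((n, n)) < density
    sums = M.sum(axis=0)
    nz = sums > 0
    M[:, nz] /= sums[nz]
    return M
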