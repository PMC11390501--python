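import numpy as np
import pytest

from cnvcomplexity.cnv_io import ContinuousCnvMatrix, DiscreteCnvMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_discrete():
    """3 genes x 2 cells with states {3,3; 5,3; 1,1}."""
    return DiscreteCnvMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["cell_1", "cell_2"],
        states=np.array([[3, 3], [5, 3], [1, 1]]),
    )


@pytest.fixture
def small_continuous():
    return ContinuousCnvMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["cell_1", "cell_2"],
        values=np.array([[1.0, 1.01], [2.0, 0.99], [0.0, 1.0]]),
    )


def random_discrete(rng, n_genes, n_cells):
    states = rng.integers(1, 7, size=(n_genes, n_cells))
    return DiscreteCnvMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        states=states,
    )
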