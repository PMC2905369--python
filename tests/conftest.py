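import numpy as np
import pytest

from svdppcs import ExpressionMatrix, simulate_pair, two_way_polish


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_ids=None, array_labels=None, **kw):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    array_labels = array_labels or [f"a{j}" for j in range(m)]
    return ExpressionMatrix(values=values, gene_ids=gene_ids, array_labels=array_labels, **kw)


@pytest.fixture
def random_polished(rng):
    """A 50 x 10 polished matrix of pure noise."""
    mat = make_matrix(rng.normal(size=(50, 10)))
    return two_way_polish(mat)


@pytest.fixture(scope="session")
def sim_pair():
    """The default two-species benchmark instance (seed 0)."""
    return simulate_pair(seed=0)
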