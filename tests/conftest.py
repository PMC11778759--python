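import numpy as np
import pytest
from hypothesis import settings

from covnet.datatypes import Network

settings.register_profile("covnet", database=None, deadline=None)
settings.load_profile("covnet")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_regression(rng):
    """20 x 3 standardized design with a sparse truth, plus intercept column."""
    X = rng.normal(size=(20, 3))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.array([1.2, 0.0, -0.7])
    y = 0.3 + X @ beta + 0.2 * rng.normal(size=20)
    A = np.hstack([np.ones((20, 1)), X])
    return A, X, y


def make_network(gene_ids, edges, weights=None):
    """Build a Network from an explicit undirected edge list."""
    p = len(gene_ids)
    index = {g: i for i, g in enumerate(gene_ids)}
    W = np.zeros((p, p))
    A = np.zeros((p, p), dtype=int)
    for k, (a, b) in enumerate(edges):
        w = 0.5 if weights is None else weights[k]
        i, j = index[a], index[b]
        W[i, j] = W[j, i] = w
        A[i, j] = A[j, i] = 1
    thr = min((abs(w) for w in W[A.astype(bool)]), default=0.0)
    return Network(gene_ids=list(gene_ids), weights=W, adjacency=A,
                   threshold_value=float(thr))
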