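import numpy as np
import pytest

from netkern import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_graph_laplacian(n, p_edge, rng):
    """Random undirected graph as (W, L) with unit-degree isolated nodes."""
    W = (rng.random((n, n)) < p_edge).astype(float)
    W = np.triu(W, 1)
    W = W + W.T
    d = W.sum(axis=1)
    d = np.where(d == 0, 1.0, d)
    return W, np.diag(d) - W


@pytest.fixture
def toy_expression(rng):
    """Small labeled expression matrix: 12 samples x 6 genes, 2 informative."""
    n, p = 12, 6
    X = rng.normal(size=(n, p))
    y = np.array([1, -1] * (n // 2))
    X[y == 1, 0] += 2.0
    X[y == 1, 1] -= 2.0
    return ExpressionMatrix(
        values=X,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(p)],
        labels=y,
    )
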