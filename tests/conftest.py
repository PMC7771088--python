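import numpy as np
import pytest

from netdrug.containers import ExpressionMatrix, ResponseTable
from netdrug.network import build_adjacency, normalize


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_expression(rng):
    """20 random genes x 30 samples, fully numeric, nonconstant."""
    vals = rng.standard_normal((20, 30))
    return ExpressionMatrix(vals, [f"g{i:02d}" for i in range(20)], [f"s{j:02d}" for j in range(30)])


@pytest.fixture
def toy_network(toy_expression):
    return normalize(build_adjacency(toy_expression))


@pytest.fixture
def toy_response(rng, toy_expression):
    vals = rng.standard_normal((2, toy_expression.n_samples))
    return ResponseTable(vals, ["dA", "dB"], list(toy_expression.sample_ids))


def chain_network():
    """3-node path graph with unit weights, as a CoexpressionNetwork."""
    from netdrug.network import CoexpressionNetwork

    A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return normalize(CoexpressionNetwork(A, ["a", "b", "c"]))
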