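import numpy as np
import pytest

from graphfae.core_data import FeatureMatrix, Graph


@pytest.fixture
def path_graph():
    """3-node path a—b—c."""
    return Graph.from_edge_pairs(("a", "b", "c"), [(0, 1), (1, 2)])


@pytest.fixture
def toy_features(path_graph):
    rng = np.random.default_rng(0)
    return FeatureMatrix(values=rng.standard_normal((3, 4)),
                         gene_ids=path_graph.node_ids,
                         experiment_ids=("e0", "e1", "e2", "e3"))


def random_graph_and_features(seed, n_max=12, q_max=5):
    """Small random instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    q = int(rng.integers(1, q_max + 1))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < 0.4]
    g = Graph.from_edge_pairs(tuple(f"n{i}" for i in range(n)), pairs)
    h = rng.standard_normal((n, q))
    return g, h
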