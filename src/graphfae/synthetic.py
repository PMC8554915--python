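"""Synthetic benchmarks: random graphs and graph-smooth feature matrices.

Real molecular networks couple topology to activity: neighbouring genes tend
to have correlated expression.  The generator reproduces exactly that
coupling — a random base signal repeatedly multiplied by the normalised
adjacency operator Ã = D^{-1/2}(A+I)D^{-1/2}, plus observation noise — so
"does the graph help feature prediction?" is testable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_data import FeatureMatrix, Graph, normalize_adjacency

__all__ = ["SyntheticSpec", "erdos_renyi_graph", "two_block_graph",
           "smooth_features", "degree_preserving_shuffle"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Default study conditions for the synthetic benchmark.

    ``generate`` emulates two features of real expression compendia: a
    graph-coupled component (each column an independent signal smoothed along
    network edges — neighbouring genes co-vary) and a gene-program component
    (a rank-``n_factors`` matrix of per-gene factors times per-experiment
    loadings — a gene's profile is predictable from its own other
    experiments).  ``graph_weight`` sets the variance share of the coupled
    component; both parts are column-standardized before i.i.d. Gaussian
    noise with sd ``noise_sd`` is added, so the noise level reads as a
    noise-to-signal ratio.
    """

    n_nodes: int = 300
    edge_prob: float = 0.05
    n_experiments: int = 20
    diffusion_steps: int = 4
    noise_sd: float = 0.3
    n_factors: int = 5
    graph_weight: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError("edge_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.graph_weight <= 1.0:
            raise ValueError("graph_weight must be in [0, 1]")

    def generate(self):
        g = erdos_renyi_graph(self.n_nodes, self.edge_prob, self.seed)
        q = self.n_experiments
        smooth = smooth_features(g, q, self.diffusion_steps, 0.0,
                                 self.seed + 1, standardize=True).values
        rng = np.random.default_rng(self.seed + 2)
        factors = rng.standard_normal((self.n_nodes, self.n_factors))
        loadings = rng.standard_normal((q, self.n_factors))
        programs = factors @ loadings.T
        programs = programs - programs.mean(axis=0, keepdims=True)
        sd = programs.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        programs = programs / sd
        w = self.graph_weight
        x = np.sqrt(w) * smooth + np.sqrt(1.0 - w) * programs
        if self.noise_sd > 0:
            x = x + self.noise_sd * rng.standard_normal(x.shape)
        return g, FeatureMatrix(values=x, gene_ids=g.node_ids,
                                experiment_ids=tuple(f"e{k}"
                                                     for k in range(q)))


def _node_names(n: int) -> tuple:
    width = len(str(max(n - 1, 0)))
    return tuple(f"g{str(i).zfill(width)}" for i in range(n))


def erdos_renyi_graph(n: int, p: float, seed: int) -> Graph:
    """G(n, p): each of the n(n−1)/2 unordered pairs is an edge independently
    with probability p.  Deterministic under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability {p} outside [0, 1]")
    gnx = nx.gnp_random_graph(n, p, seed=int(seed))
    return Graph.from_edge_pairs(_node_names(n), gnx.edges())


def two_block_graph(n: int, p_in: float, p_out: float, seed: int) -> Graph:
    """Two equal communities: pair probability p_in within blocks, p_out
    between.  A planted structure the graph auto-encoder can learn, unlike a
    homogeneous G(n, p)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    sizes = [n // 2, n - n // 2]
    gnx = nx.stochastic_block_model(
        sizes, [[p_in, p_out], [p_out, p_in]], seed=int(seed))
    return Graph.from_edge_pairs(_node_names(n), gnx.edges())


def smooth_features(g: Graph, q: int, steps: int, noise_sd: float,
                    seed: int, standardize: bool = False) -> FeatureMatrix:
    """N×Q feature matrix whose columns are graph-smooth signals.

    Draws i.i.d. standard-normal base columns, applies Ã ``steps`` times
    (each application contracts the signal toward the leading eigenvectors of
    Ã, i.e. smooths it along edges) and adds i.i.d. N(0, noise_sd²) noise.

    With ``standardize`` each diffused column is rescaled to zero mean and
    unit variance before the noise is added, so ``noise_sd`` reads as a
    noise-to-signal ratio regardless of how strongly the operator contracts.
    Without it the raw diffusion output is returned, whose variance shrinks
    with ``steps``.
    """
    if g.n_nodes == 0:
        raise ValueError("graph must be nonempty")
    if q < 1:
        raise ValueError("q must be >= 1")
    rng = np.random.default_rng(int(seed))
    base = rng.standard_normal((g.n_nodes, q))
    a_norm = normalize_adjacency(g)
    signal = base
    for _ in range(int(steps)):
        signal = a_norm @ signal
    if standardize:
        signal = signal - signal.mean(axis=0, keepdims=True)
        sd = signal.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        signal = signal / sd
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(signal.shape)
    return FeatureMatrix(values=signal, gene_ids=g.node_ids,
                         experiment_ids=tuple(f"e{k}" for k in range(q)))


def degree_preserving_shuffle(g: Graph, seed: int, n_swaps: int | None = None
                              ) -> Graph:
    """Randomise edges while preserving every node's degree (double edge
    swaps).  Serves as the topology-destroying control: same degree sequence,
    scrambled neighbourhoods."""
    gnx = nx.Graph()
    gnx.add_nodes_from(range(g.n_nodes))
    gnx.add_edges_from(tuple(e) for e in g.edge_array())
    m = gnx.number_of_edges()
    if m < 2:
        return g
    if n_swaps is None:
        n_swaps = 10 * m
    nx.double_edge_swap(gnx, nswap=n_swaps, max_tries=100 * n_swaps,
                        seed=int(seed))
    return Graph.from_edge_pairs(g.node_ids, gnx.edges())
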