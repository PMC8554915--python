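"""Domain types and plumbing shared by every stage.

A molecular interaction network is an undirected, unweighted :class:`Graph`
over named nodes (genes or proteins); node activity measurements across
experiments or cells form a :class:`FeatureMatrix` X ∈ ℝ^{N×Q}.  Both sides
are read from plain TSV files, restricted to their common genes, and the
graph is turned into the symmetrically normalised propagation operator
Ã = D^{-1/2}(A + I)D^{-1/2} that every convolution layer uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("graphfae")

__all__ = [
    "Graph", "FeatureMatrix", "MaskPair", "MaskMode", "EdgeSplit",
    "read_edge_list", "write_edge_list", "read_expression_table",
    "write_expression_table", "align_graph_and_features",
    "normalize_adjacency", "masked_mse",
]


@dataclass(frozen=True)
class Graph:
    """Undirected, unweighted graph with a stable node-ID map.

    Edges are stored as a frozenset of unordered index pairs; indices refer to
    positions in ``node_ids``.  Self-pairs and duplicates are excluded by
    construction.
    """

    node_ids: tuple
    edges: frozenset  # of frozenset({i, j}) pairs, i != j

    def __post_init__(self):
        n = len(self.node_ids)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge {set(e)} is not a pair of distinct nodes")
            if any(i < 0 or i >= n for i in e):
                raise ValueError(f"edge {set(e)} has index outside [0, {n})")

    @classmethod
    def from_edge_pairs(cls, node_ids, pairs):
        """Build a graph from (i, j) index pairs, dropping self-pairs and
        deduplicating undirected duplicates."""
        node_ids = tuple(node_ids)
        edges = set()
        n_self = n_dup = 0
        for i, j in pairs:
            if i == j:
                n_self += 1
                continue
            e = frozenset((int(i), int(j)))
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
        if n_self:
            logger.warning("dropped %d self-edge(s)", n_self)
        if n_dup:
            logger.info("deduplicated %d repeated edge(s)", n_dup)
        return cls(node_ids=node_ids, edges=frozenset(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted (|E|, 2) int array with i < j, for determinism."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        arr = np.array(sorted(tuple(sorted(e)) for e in self.edges),
                       dtype=np.int64)
        return arr

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix without self-loops (CSR)."""
        n = self.n_nodes
        e = self.edge_array()
        if e.size == 0:
            return sp.csr_matrix((n, n))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))

    def has_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.edges


@dataclass(frozen=True)
class FeatureMatrix:
    """Node-feature table: N genes × Q experiments of real values."""

    values: np.ndarray
    gene_ids: tuple
    experiment_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if v.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(self.gene_ids)} genes "
                f"and {len(self.experiment_ids)} experiments")
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)


class MaskMode(Enum):
    EXPERIMENT_SPLIT = "experiment_split"
    IMPUTATION = "imputation"


@dataclass(frozen=True)
class MaskPair:
    """Binary train/test masks over an N×Q feature matrix.

    In IMPUTATION mode the two masks partition the eligible-entry set; in
    EXPERIMENT_SPLIT mode they mark train-gene and test-gene rows of the
    held-out target column.
    """

    train_mask: np.ndarray
    test_mask: np.ndarray
    mode: MaskMode
    input_columns: tuple = ()
    target_columns: tuple = ()

    def __post_init__(self):
        tr = np.asarray(self.train_mask, dtype=np.float64)
        te = np.asarray(self.test_mask, dtype=np.float64)
        object.__setattr__(self, "train_mask", tr)
        object.__setattr__(self, "test_mask", te)
        if tr.shape != te.shape:
            raise ValueError("train and test masks must share a shape")
        for m in (tr, te):
            if not np.isin(m, (0.0, 1.0)).all():
                raise ValueError("masks must be binary")
        if (tr * te).any():
            raise ValueError("train and test masks overlap")


@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint train/val/test positive edges plus sampled negative pairs."""

    train_pos: np.ndarray  # (m, 2) int arrays, i < j
    val_pos: np.ndarray
    test_pos: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray

    def train_graph(self, n_nodes: int, node_ids=None) -> Graph:
        ids = tuple(node_ids) if node_ids is not None else tuple(range(n_nodes))
        return Graph.from_edge_pairs(ids, [tuple(e) for e in self.train_pos])


# ---------------------------------------------------------------------------
# File I/O

def read_edge_list(path, delimiter="\t") -> Graph:
    """Read a two-column edge list (``#`` comments allowed) into a Graph.

    Node order is first-appearance order; undirected duplicates are merged and
    self-edges dropped with a warning.
    """
    ids: dict = {}
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter != " " else line.split()
            if delimiter == "\t" and len(parts) < 2:
                parts = line.split()  # tolerate space-separated files
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} has fewer than 2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            for g in (a, b):
                if g not in ids:
                    ids[g] = len(ids)
            pairs.append((ids[a], ids[b]))
    return Graph.from_edge_pairs(tuple(ids), pairs)


def write_edge_list(g: Graph, path, delimiter="\t") -> None:
    with open(path, "w") as fh:
        for i, j in g.edge_array():
            fh.write(f"{g.node_ids[i]}{delimiter}{g.node_ids[j]}\n")


def read_expression_table(path) -> FeatureMatrix:
    """Read a TSV expression table: header = experiment IDs, first column =
    gene IDs, numeric body."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ID(s): {dups}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return FeatureMatrix(values=values,
                         gene_ids=tuple(str(g) for g in df.index),
                         experiment_ids=tuple(str(c) for c in df.columns))


def write_expression_table(x: FeatureMatrix, path) -> None:
    df = pd.DataFrame(x.values, index=list(x.gene_ids),
                      columns=list(x.experiment_ids))
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Alignment and operators

def align_graph_and_features(g: Graph, x: FeatureMatrix):
    """Restrict graph and features to their common genes.

    Output node order is sorted by gene ID for run-to-run determinism; edges
    with an endpoint outside the intersection are dropped.
    """
    if g.n_nodes == 0 or x.n_genes == 0:
        raise ValueError("cannot align empty inputs")
    common = sorted(set(g.node_ids) & set(x.gene_ids))
    if not common:
        raise ValueError("graph and feature matrix share no gene IDs")
    new_index = {gid: k for k, gid in enumerate(common)}
    keep = set(common)
    pairs = []
    for i, j in g.edge_array():
        gi, gj = g.node_ids[i], g.node_ids[j]
        if gi in keep and gj in keep:
            pairs.append((new_index[gi], new_index[gj]))
    g2 = Graph.from_edge_pairs(tuple(common), pairs)
    feat_index = {gid: k for k, gid in enumerate(x.gene_ids)}
    rows = [feat_index[gid] for gid in common]
    x2 = FeatureMatrix(values=x.values[rows, :], gene_ids=tuple(common),
                       experiment_ids=x.experiment_ids)
    return g2, x2


def normalize_adjacency(g: Graph) -> sp.csr_matrix:
    """Symmetrically normalised adjacency with self-loops:
    Ã = D^{-1/2}(A + I)D^{-1/2}, D recomputed from A + I.

    Isolated nodes get degree 1 from their self-loop, so Ã is always defined.
    """
    if g.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    a = g.adjacency() + sp.identity(g.n_nodes, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    d = sp.diags(d_inv_sqrt)
    return sp.csr_matrix(d @ a @ d)


def mean_aggregation_operator(g: Graph) -> sp.csr_matrix:
    """Row-stochastic closed-neighbourhood mean operator D̃^{-1}(A + I)."""
    a = g.adjacency() + sp.identity(g.n_nodes, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    return sp.csr_matrix(sp.diags(1.0 / deg) @ a)


def masked_mse(pred, target, mask) -> float:
    """Mean squared error restricted to mask-selected entries."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if not (pred.shape == target.shape == mask.shape):
        raise ValueError("pred, target and mask shapes must agree")
    m = mask.sum()
    if m == 0:
        raise ValueError("mask selects no entries")
    diff = np.where(mask > 0, pred - target, 0.0)
    return float((diff ** 2).sum() / m)
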