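"""Structural graph auto-encoder (GAE).

A two-layer graph convolutional encoder maps nodes to a low-dimensional
embedding Z = Ã·ReLU(Ã·X·W₀)·W₁; an inner-product decoder Â = σ(ZZᵀ) scores
node pairs as edge probabilities.  Training minimises a class-reweighted
binary cross-entropy between Â and the (train-split) adjacency.  The
embedding is evaluated by held-out link prediction (AUC/AP), by the fraction
of feature variance a linear readout explains, and as input to indirect
regression of node features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from . import _autodiff as ad
from .core_data import EdgeSplit, FeatureMatrix, Graph, normalize_adjacency

__all__ = [
    "GaeConfig", "GaeWeights", "GraphAutoEncoder", "gcn_encode",
    "decode_adjacency", "reconstruction_loss", "split_edges", "train_gae",
    "evaluate_link_prediction", "variance_explained",
    "correlation_edge_scores", "indirect_predict", "identity_features",
]


@dataclass
class GaeConfig:
    """Node-embedding hyper-parameters (defaults: 500 epochs, lr 1e-3,
    hidden sizes 64 and 32)."""

    epochs: int = 500
    learning_rate: float = 0.001
    hidden1: int = 64
    hidden2: int = 32
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.hidden1 < 1 or self.hidden2 < 1:
            raise ValueError("epochs and hidden sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class GaeWeights:
    """Trainable encoder weights W₀ (Q_in×h1) and W₁ (h1×d)."""

    w0: np.ndarray
    w1: np.ndarray


def identity_features(n: int) -> np.ndarray:
    """One-hot (identity) input features: each node gets a distinct,
    functionally meaningless feature vector, so the encoder can only exploit
    graph structure."""
    return np.eye(n)


def _as_values(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.asarray(x, dtype=np.float64)


def gcn_encode(x, a_norm, w: GaeWeights) -> np.ndarray:
    """Two-layer GCN encoder: Z = Ã·ReLU(Ã·X·W₀)·W₁ (output activation is
    the identity)."""
    xv = _as_values(x)
    if xv.shape[0] != a_norm.shape[0]:
        raise ValueError("feature rows must match graph size")
    if xv.shape[1] != w.w0.shape[0]:
        raise ValueError("W0 input dimension must match feature count")
    h = a_norm @ (xv @ w.w0)
    h = np.maximum(h, 0.0)
    return a_norm @ (h @ w.w1)


def decode_adjacency(z, pairs) -> np.ndarray:
    """Edge probabilities σ(z_i · z_j) for each requested pair."""
    z = _as_values(z)
    pairs = np.asarray(pairs, dtype=np.int64)
    if pairs.size == 0:
        return np.empty(0)
    logits = np.einsum("ij,ij->i", z[pairs[:, 0]], z[pairs[:, 1]])
    return 1.0 / (1.0 + np.exp(-logits))


def _adjacency_label(g: Graph) -> np.ndarray:
    """Reconstruction target: adjacency with unit diagonal (self-loops are
    positives, since z_i·z_i ≥ 0 for an inner-product decoder)."""
    return g.adjacency().toarray() + np.eye(g.n_nodes)


def _pos_weight(n: int, n_edges: int) -> float:
    if n_edges == 0:
        raise ValueError("pos_weight undefined for a graph with no edges")
    n_pos = 2.0 * n_edges + n  # symmetric edges plus the unit diagonal
    return (n * n - n_pos) / n_pos


def reconstruction_loss(z, g: Graph) -> float:
    """Class-reweighted binary cross-entropy between σ(ZZᵀ) and the
    self-loop-augmented adjacency, averaged over all N² entries; the
    positive class is reweighted to counter edge sparsity."""
    z = _as_values(z)
    if z.shape[0] != g.n_nodes:
        raise ValueError("embedding rows must match graph size")
    a = _adjacency_label(g)
    pw = _pos_weight(g.n_nodes, g.n_edges)
    zt = ad.Tensor(z)
    return float(ad.inner_product_bce(zt, a, pw).data)


def split_edges(g: Graph, val_frac: float, test_frac: float,
                seed: int) -> EdgeSplit:
    """Uniform random partition of the edge set into train/val/test, with
    negative (non-edge) pairs sampled to match the val/test positives."""
    if val_frac + test_frac >= 1.0:
        raise ValueError("val_frac + test_frac must be < 1")
    edges = g.edge_array()
    m = len(edges)
    n_val = int(np.floor(m * val_frac))
    n_test = int(np.floor(m * test_frac))
    if m - n_val - n_test < 1:
        raise ValueError("too few edges for the requested split")
    rng = np.random.default_rng(int(seed))
    perm = rng.permutation(m)
    val_pos = edges[perm[:n_val]]
    test_pos = edges[perm[n_val:n_val + n_test]]
    train_pos = edges[perm[n_val + n_test:]]

    n = g.n_nodes
    needed = n_val + n_test
    negatives = []
    seen = set(map(tuple, edges))
    max_possible = n * (n - 1) // 2 - m
    if needed > max_possible:
        raise ValueError("graph too dense to sample enough negative pairs")
    while len(negatives) < needed:
        cand = rng.integers(0, n, size=(max(4 * (needed - len(negatives)), 16), 2))
        for i, j in cand:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            negatives.append(key)
            if len(negatives) == needed:
                break
    negatives = np.array(negatives, dtype=np.int64).reshape(needed, 2)
    return EdgeSplit(train_pos=train_pos, val_pos=val_pos, test_pos=test_pos,
                     val_neg=negatives[:n_val], test_neg=negatives[n_val:])


def train_gae(x_input, g: Graph, split: EdgeSplit | None, cfg: GaeConfig):
    """Train the GAE by Adam on the reconstruction loss of the training
    graph (Ã is built from train edges only when a split is given).

    Returns ``(Z, GaeWeights, loss_curve)``; deterministic under cfg.seed.
    """
    xv = _as_values(x_input)
    n = g.n_nodes
    if xv.shape[0] != n:
        raise ValueError("features and graph are not aligned")
    train_g = split.train_graph(n, g.node_ids) if split is not None else g
    if train_g.n_edges == 0:
        raise ValueError("training graph has no edges")
    a_norm = normalize_adjacency(train_g)
    a_label = _adjacency_label(train_g)
    pw = _pos_weight(n, train_g.n_edges)

    rng = np.random.default_rng(int(cfg.seed))
    w0 = ad.glorot(rng, xv.shape[1], cfg.hidden1)
    w1 = ad.glorot(rng, cfg.hidden1, cfg.hidden2)
    opt = ad.Adam([w0, w1], lr=cfg.learning_rate)
    x_t = ad.Tensor(xv)
    losses = []
    for epoch in range(cfg.epochs):
        h = ad.relu(ad.spmm(a_norm, ad.matmul(x_t, w0)))
        if cfg.dropout > 0:
            keep = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h = ad.mul_const(h, keep)
        z = ad.spmm(a_norm, ad.matmul(h, w1))
        loss = ad.inner_product_bce(z, a_label, pw)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        losses.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    weights = GaeWeights(w0=w0.data.copy(), w1=w1.data.copy())
    z_final = gcn_encode(xv, a_norm, weights)
    return z_final, weights, np.array(losses)


def evaluate_link_prediction(scores_pos, scores_neg):
    """AUC (probability a true edge outscores a non-edge, ties at ½) and
    average precision over held-out positives vs sampled negatives."""
    scores_pos = np.asarray(scores_pos, dtype=np.float64)
    scores_neg = np.asarray(scores_neg, dtype=np.float64)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    y = np.concatenate([np.ones(scores_pos.size), np.zeros(scores_neg.size)])
    s = np.concatenate([scores_pos, scores_neg])
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


def variance_explained(z, x) -> float:
    """Fraction of total feature variance captured by a linear readout from
    the embedding: R² of the joint OLS fit X ≈ [Z, 1]·B, with the total sum
    of squares taken about column means."""
    z = _as_values(z)
    xv = _as_values(x)
    if z.shape[0] != xv.shape[0]:
        raise ValueError("embedding and features must have equal row counts")
    design = np.column_stack([z, np.ones(z.shape[0])])
    coef, *_ = np.linalg.lstsq(design, xv, rcond=None)
    resid = xv - design @ coef
    ss_res = float((resid ** 2).sum())
    centered = xv - xv.mean(axis=0, keepdims=True)
    ss_tot = float((centered ** 2).sum())
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def correlation_edge_scores(x, pairs) -> np.ndarray:
    """Score candidate edges by the absolute Pearson correlation of the two
    genes' expression profiles (the coexpression-network baseline).  Rows of
    zero variance score 0."""
    xv = _as_values(x)
    if xv.shape[1] < 2:
        raise ValueError("need at least 2 experiments to correlate")
    pairs = np.asarray(pairs, dtype=np.int64)
    centered = xv - xv.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    scores = np.zeros(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if norms[i] == 0 or norms[j] == 0:
            continue
        scores[k] = abs(float(centered[i] @ centered[j]) / (norms[i] * norms[j]))
    return scores


def indirect_predict(z, y_train, train_nodes, test_nodes, regressor="LR",
                     seed=0, n_trees=100):
    """Fit a regressor from embedding rows to a target value on train nodes
    and predict the test nodes (the indirect, embedding-based route)."""
    z = _as_values(z)
    train_nodes = np.asarray(train_nodes, dtype=np.int64)
    test_nodes = np.asarray(test_nodes, dtype=np.int64)
    if set(train_nodes.tolist()) & set(test_nodes.tolist()):
        raise ValueError("train and test node sets overlap")
    y_train = np.asarray(y_train, dtype=np.float64)
    if regressor == "LR":
        model = LinearRegression()
    elif regressor == "RF":
        model = RandomForestRegressor(n_estimators=n_trees,
                                      random_state=int(seed))
    else:
        raise ValueError(f"unknown regressor {regressor!r}; use 'LR' or 'RF'")
    model.fit(z[train_nodes], y_train)
    return model.predict(z[test_nodes])


class GraphAutoEncoder(BaseEstimator):
    """sklearn-style estimator wrapping the structural GAE.

    Parameters mirror :class:`GaeConfig`.  ``fit(X, graph=...)`` trains the
    encoder on the graph's (optionally split) adjacency with X as node
    features (pass ``X=None`` for identity features); ``transform`` returns
    the node embedding for the fitted graph.

    Attributes
    ----------
    embedding_ : (N, hidden2) ndarray
    weights_ : GaeWeights
    loss_curve_ : (epochs,) ndarray
    split_ : EdgeSplit or None
    """

    def __init__(self, epochs=500, learning_rate=0.001, hidden1=64,
                 hidden2=32, dropout=0.0, val_frac=0.05, test_frac=0.10,
                 use_edge_split=True, seed=0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.dropout = dropout
        self.val_frac = val_frac
        self.test_frac = test_frac
        self.use_edge_split = use_edge_split
        self.seed = seed

    def _config(self) -> GaeConfig:
        return GaeConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                         hidden1=self.hidden1, hidden2=self.hidden2,
                         dropout=self.dropout, seed=self.seed)

    def fit(self, X, y=None, *, graph: Graph):
        xv = identity_features(graph.n_nodes) if X is None else _as_values(X)
        split = None
        if self.use_edge_split:
            split = split_edges(graph, self.val_frac, self.test_frac,
                                self.seed)
        z, w, curve = train_gae(xv, graph, split, self._config())
        self.graph_ = graph
        self.split_ = split
        self.embedding_ = z
        self.weights_ = w
        self.loss_curve_ = curve
        return self

    def transform(self, X=None):
        self._check_fitted()
        return self.embedding_

    def predict_proba_pairs(self, pairs):
        """Edge probabilities for node-index pairs from the fitted embedding."""
        self._check_fitted()
        return decode_adjacency(self.embedding_, pairs)

    def score_link_prediction(self, which="test"):
        """(AUC, AP) on the held-out positive vs negative pairs."""
        self._check_fitted()
        if self.split_ is None:
            raise ValueError("estimator was fitted without an edge split")
        pos = self.split_.test_pos if which == "test" else self.split_.val_pos
        neg = self.split_.test_neg if which == "test" else self.split_.val_neg
        return evaluate_link_prediction(decode_adjacency(self.embedding_, pos),
                                        decode_adjacency(self.embedding_, neg))

    def variance_explained(self, X) -> float:
        self._check_fitted()
        return variance_explained(self.embedding_, X)

    def _check_fitted(self):
        if not hasattr(self, "embedding_"):
            raise ValueError("GraphAutoEncoder is not fitted; call fit first")
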