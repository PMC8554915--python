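"""Message-passing layers and the end-to-end Graph Feature Auto-Encoder.

Four neighbourhood-aggregation schemes update node states h_i (weights act on
the right, W of shape (in_dim, out_dim)):

* ``gcn``           h'_i = Σ_{j∈N(i)∪i} (deg(i)·deg(j))^{-1/2} · hⱼW,
                    degrees counted with self-loops — one dense GCN layer.
* ``sage``          h'_i = h_iW₁ + Mean_{j∈N(i)∪i}(hⱼ)·W₂  (GraphSAGE with
                    the self node included in the mean).
* ``graphconv``     h'_i = h_iW₁ + Σ_{j∈N(i)} hⱼW₂  (sum over open
                    neighbourhood).
* ``featgraphconv`` gᵢ = hᵢW₁;  h'_i = (gᵢ ‖ Mean_{j∈N(i)∪i} gⱼ)·W₂ —
                    FeatGraphConv: a linear message transform, closed-
                    neighbourhood mean pooling, and a shared update on the
                    concatenation of self and pooled messages, designed for
                    feature (not structure) reconstruction.

A ``dense`` kind with no message passing gives the plain MLP auto-encoder
used as the graph-free control.  The full network is two such layers
(input→64→32, ReLU after each) and an affine readout x̃ᵢ = Whᵢ + b, trained
end-to-end by Adam on mean squared error over the observed (masked-in)
entries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from .core_data import (FeatureMatrix, Graph, mean_aggregation_operator,
                        normalize_adjacency)

__all__ = [
    "LayerKind", "GfaeConfig", "GfaeNetwork", "GFAEImputer",
    "gcn_mp_layer", "sage_layer", "graphconv_layer", "featgraphconv_layer",
    "readout", "build_gfae", "train_gfae", "predict_gfae",
]


class LayerKind(Enum):
    GCN_MP = "gcn"
    GRAPHSAGE = "sage"
    GRAPHCONV = "graphconv"
    FEATGRAPHCONV = "featgraphconv"
    DENSE = "dense"  # no message passing: the MLP auto-encoder control

    @classmethod
    def coerce(cls, value) -> "LayerKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown layer kind {value!r}; choose from "
                f"{[k.value for k in cls]}") from None


@dataclass
class GfaeConfig:
    """End-to-end training hyper-parameters (full-run default: 20000 epochs
    at lr 1e-3; pass fewer epochs for quick profiles)."""

    epochs: int = 20000
    learning_rate: float = 0.001
    hidden1: int = 64
    hidden2: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.hidden1 < 1 or self.hidden2 < 1:
            raise ValueError("epochs and hidden sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# Functional layer forms (NumPy in, NumPy out) — the per-layer contracts.

def _check_dims(h, w_in):
    if h.shape[1] != w_in:
        raise ValueError(f"feature dim {h.shape[1]} does not match weight "
                         f"input dim {w_in}")


def gcn_mp_layer(h, g: Graph, w) -> np.ndarray:
    """Symmetrically normalised sum aggregation (degrees include the
    self-loop); identical to one application of Ã·H·W."""
    h = np.asarray(h, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    _check_dims(h, w.shape[0])
    return normalize_adjacency(g) @ (h @ w)


def sage_layer(h, g: Graph, w1, w2) -> np.ndarray:
    """Self transform plus transformed closed-neighbourhood mean."""
    h = np.asarray(h, dtype=np.float64)
    w1, w2 = np.asarray(w1, np.float64), np.asarray(w2, np.float64)
    _check_dims(h, w1.shape[0])
    _check_dims(h, w2.shape[0])
    return h @ w1 + (mean_aggregation_operator(g) @ h) @ w2


def graphconv_layer(h, g: Graph, w1, w2) -> np.ndarray:
    """Self transform plus summed neighbour messages (self excluded)."""
    h = np.asarray(h, dtype=np.float64)
    w1, w2 = np.asarray(w1, np.float64), np.asarray(w2, np.float64)
    _check_dims(h, w1.shape[0])
    _check_dims(h, w2.shape[0])
    return h @ w1 + (g.adjacency() @ h) @ w2


def featgraphconv_layer(h, g: Graph, w1, w2) -> np.ndarray:
    """FeatGraphConv: transform, mean-pool over the closed neighbourhood,
    concatenate self with pooled messages, shared linear update."""
    h = np.asarray(h, dtype=np.float64)
    w1, w2 = np.asarray(w1, np.float64), np.asarray(w2, np.float64)
    _check_dims(h, w1.shape[0])
    if w2.shape[0] != 2 * w1.shape[1]:
        raise ValueError("W2 input dim must be twice W1 output dim")
    msg = h @ w1
    pooled = mean_aggregation_operator(g) @ msg
    return np.concatenate([msg, pooled], axis=1) @ w2


def readout(h, w, b) -> np.ndarray:
    """Affine readout x̃ᵢ = Whᵢ + b (no output nonlinearity)."""
    h = np.asarray(h, dtype=np.float64)
    w, b = np.asarray(w, np.float64), np.asarray(b, np.float64)
    _check_dims(h, w.shape[0])
    return h @ w + b


# ---------------------------------------------------------------------------
# Network assembly and training.

@dataclass
class GfaeNetwork:
    """Two convolution layers (ReLU after each) plus an affine readout."""

    layer_kind: LayerKind
    input_dim: int
    output_dim: int
    hidden1: int
    hidden2: int
    params: dict = field(default_factory=dict)  # name -> ad.Tensor

    def parameters(self):
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _conv(self, layer: int, h: ad.Tensor, ops) -> ad.Tensor:
        k = self.layer_kind
        p = self.params
        if k is LayerKind.GCN_MP:
            return ad.spmm(ops["anorm"], ad.matmul(h, p[f"w{layer}"]))
        if k is LayerKind.GRAPHSAGE:
            return _add(ad.matmul(h, p[f"w{layer}_self"]),
                        ad.matmul(ad.spmm(ops["mean"], h), p[f"w{layer}_nbr"]))
        if k is LayerKind.GRAPHCONV:
            return _add(ad.matmul(h, p[f"w{layer}_self"]),
                        ad.matmul(ad.spmm(ops["adj"], h), p[f"w{layer}_nbr"]))
        if k is LayerKind.FEATGRAPHCONV:
            msg = ad.matmul(h, p[f"w{layer}_msg"])
            pooled = ad.spmm(ops["mean"], msg)
            return ad.matmul(ad.concat(msg, pooled), p[f"w{layer}_upd"])
        if k is LayerKind.DENSE:
            return ad.matmul(h, p[f"w{layer}"])
        raise ValueError(f"unknown layer kind {k}")

    def forward(self, x: ad.Tensor, ops) -> ad.Tensor:
        h = ad.relu(self._conv(1, x, ops))
        h = ad.relu(self._conv(2, h, ops))
        return ad.add_bias(ad.matmul(h, self.params["w_out"]),
                           self.params["b_out"])


def _add(a: ad.Tensor, b: ad.Tensor) -> ad.Tensor:
    data = a.data + b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    out = ad.Tensor(data)
    out.requires_grad = True
    out._parents = (a, b)
    out._backward = backward
    return out


def graph_operators(g: Graph | None) -> dict:
    if g is None:
        return {}
    return {"anorm": normalize_adjacency(g),
            "mean": mean_aggregation_operator(g),
            "adj": g.adjacency()}


def build_gfae(layer_kind, input_dim: int, output_dim: int, seed: int,
               hidden1: int = 64, hidden2: int = 32) -> GfaeNetwork:
    """Construct a seeded GFAE network of the requested layer kind
    (input→hidden1→hidden2→output)."""
    kind = LayerKind.coerce(layer_kind)
    if input_dim < 1 or output_dim < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(int(seed))
    p = {}
    dims = [(1, input_dim, hidden1), (2, hidden1, hidden2)]
    for layer, d_in, d_out in dims:
        if kind in (LayerKind.GCN_MP, LayerKind.DENSE):
            p[f"w{layer}"] = ad.glorot(rng, d_in, d_out)
        elif kind in (LayerKind.GRAPHSAGE, LayerKind.GRAPHCONV):
            p[f"w{layer}_self"] = ad.glorot(rng, d_in, d_out)
            p[f"w{layer}_nbr"] = ad.glorot(rng, d_in, d_out)
        elif kind is LayerKind.FEATGRAPHCONV:
            p[f"w{layer}_msg"] = ad.glorot(rng, d_in, d_out)
            p[f"w{layer}_upd"] = ad.glorot(rng, 2 * d_out, d_out)
    p["w_out"] = ad.glorot(rng, hidden2, output_dim)
    p["b_out"] = ad.Tensor(np.zeros(output_dim), requires_grad=True)
    return GfaeNetwork(layer_kind=kind, input_dim=input_dim,
                       output_dim=output_dim, hidden1=hidden1,
                       hidden2=hidden2, params=p)


def _values(x):
    return x.values if isinstance(x, FeatureMatrix) else np.asarray(
        x, dtype=np.float64)


def train_gfae(net: GfaeNetwork, x_input, target, train_mask,
               g: Graph | None, cfg: GfaeConfig):
    """Train a GFAE end-to-end by Adam on masked MSE with full-graph message
    passing at every step.  Returns ``(net, loss_curve)``; deterministic
    under the seeded initial weights."""
    xv = _values(x_input)
    tv = _values(target)
    mask = np.asarray(train_mask, dtype=np.float64)
    if mask.sum() == 0:
        raise ValueError("training mask selects no entries")
    if g is not None and xv.shape[0] != g.n_nodes:
        raise ValueError("features and graph are not aligned")
    ops = graph_operators(g)
    if net.layer_kind is not LayerKind.DENSE and not ops:
        raise ValueError("graph required for message-passing layers")
    x_t = ad.Tensor(xv)
    opt = ad.Adam(net.parameters(), lr=cfg.learning_rate)
    losses = []
    for epoch in range(cfg.epochs):
        pred = net.forward(x_t, ops)
        loss = ad.masked_mse_loss(pred, tv, mask)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        losses.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    return net, np.array(losses)


def predict_gfae(net: GfaeNetwork, x_input, g: Graph | None) -> np.ndarray:
    """Deterministic forward pass; the caller selects which entries to use."""
    xv = _values(x_input)
    ops = graph_operators(g)
    return net.forward(ad.Tensor(xv), ops).data


class GFAEImputer(BaseEstimator):
    """sklearn-style imputer: reconstruct a feature matrix from a partially
    observed copy using graph message passing.

    ``fit(X, graph=..., observed_mask=...)`` trains on the observed entries
    (unobserved entries are zeroed on input, the auto-encoder placeholder);
    ``transform`` returns the fully imputed matrix.

    Parameters
    ----------
    layer : str — one of gcn / sage / graphconv / featgraphconv / dense.
    epochs, learning_rate, hidden1, hidden2, seed : training controls.

    Attributes
    ----------
    network_ : GfaeNetwork
    loss_curve_ : (epochs,) ndarray
    """

    def __init__(self, layer="featgraphconv", epochs=2000,
                 learning_rate=0.001, hidden1=64, hidden2=32, seed=0):
        self.layer = layer
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.seed = seed

    def fit(self, X, y=None, *, graph: Graph | None = None,
            observed_mask=None):
        xv = _values(X)
        n, q = xv.shape
        mask = (np.ones_like(xv) if observed_mask is None
                else np.asarray(observed_mask, dtype=np.float64))
        cfg = GfaeConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                         hidden1=self.hidden1, hidden2=self.hidden2,
                         seed=self.seed)
        net = build_gfae(self.layer, q, q, self.seed, self.hidden1,
                         self.hidden2)
        net, curve = train_gfae(net, xv * mask, xv, mask, graph, cfg)
        self.graph_ = graph
        self.observed_mask_ = mask
        self.network_ = net
        self.loss_curve_ = curve
        return self

    def transform(self, X):
        if not hasattr(self, "network_"):
            raise ValueError("GFAEImputer is not fitted; call fit first")
        xv = _values(X)
        mask = (self.observed_mask_ if xv.shape == self.observed_mask_.shape
                else np.ones_like(xv))
        return predict_gfae(self.network_, xv * mask, self.graph_)

    def fit_transform(self, X, y=None, **fit_kwargs):
        return self.fit(X, y, **fit_kwargs).transform(X)
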