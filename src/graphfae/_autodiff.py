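"""Minimal reverse-mode automatic differentiation on dense NumPy arrays.

Supports exactly the operations the graph auto-encoder and the graph feature
auto-encoder need: dense and sparse-dense matrix products, broadcast bias
addition, ReLU, column concatenation, elementwise products with constants,
masked mean-squared error, and a weighted binary cross-entropy on inner-product
logits.  Gradients are accumulated by a topological backward sweep; parameters
are updated with Adam.

Sparse operands (scipy CSR) are always constants — the graph operator never
carries gradient — so only the dense side participates in backpropagation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Adam", "matmul", "spmm", "add_bias", "relu", "concat",
           "mul_const", "masked_mse_loss", "inner_product_bce"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None


def _node(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return _node(data, (a, b), backward)


def spmm(s, x: Tensor) -> Tensor:
    """Sparse constant matrix times dense tensor; gradient flows via sᵀ."""
    s = sp.csr_matrix(s)
    data = s @ x.data

    def backward(g):
        x._accumulate(s.T @ g)

    return _node(data, (x,), backward)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    data = x.data + b.data  # b broadcasts over rows

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(g)
        if b.requires_grad or b._parents:
            b._accumulate(g.sum(axis=0))

    return _node(data, (x, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def backward(g):
        x._accumulate(g * mask)

    return _node(data, (x,), backward)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Column-wise concatenation [a ‖ b]."""
    data = np.concatenate([a.data, b.data], axis=1)
    na = a.data.shape[1]

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g[:, :na])
        if b.requires_grad or b._parents:
            b._accumulate(g[:, na:])

    return _node(data, (a, b), backward)


def mul_const(x: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=np.float64)
    data = x.data * c

    def backward(g):
        x._accumulate(g * c)

    return _node(data, (x,), backward)


def masked_mse_loss(pred: Tensor, target, mask) -> Tensor:
    """Mean squared error over mask-selected entries only."""
    target = np.asarray(target, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    m = mask.sum()
    if m == 0:
        raise ValueError("mask selects no entries")
    # where() rather than multiply: masked-out entries may hold NaN
    diff = np.where(mask > 0, pred.data - target, 0.0)
    data = np.array((diff ** 2).sum() / m)

    def backward(g):
        pred._accumulate(g * 2.0 * diff / m)

    return _node(data, (pred,), backward)


def inner_product_bce(z: Tensor, adj, pos_weight: float) -> Tensor:
    """Weighted binary cross-entropy between sigmoid(Z Zᵀ) and a dense 0/1
    adjacency target, averaged over all N² entries with the positive class
    reweighted by ``pos_weight``.

    Uses the softplus form for numerical stability:
    ℓ(s, a) = pw·a·softplus(−s) + (1−a)·softplus(s).
    """
    a = np.asarray(adj, dtype=np.float64)
    n = a.shape[0]
    s = z.data @ z.data.T
    sp_pos = np.logaddexp(0.0, -s)  # softplus(−s)
    sp_neg = np.logaddexp(0.0, s)   # softplus(s)
    loss = (pos_weight * a * sp_pos + (1.0 - a) * sp_neg).sum() / (n * n)
    data = np.array(loss)
    sig = np.exp(-sp_pos)  # stable sigmoid: exp(-softplus(-s))
    # dℓ/ds = −pw·a·σ(−s) + (1−a)·σ(s)
    dl_ds = (-pos_weight * a * (1.0 - sig) + (1.0 - a) * sig) / (n * n)

    def backward(g):
        z._accumulate(g * ((dl_ds + dl_ds.T) @ z.data))

    return _node(data, (z,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors (deterministic)."""

    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    """Glorot/Xavier uniform initialisation, seeded."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                  requires_grad=True)
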