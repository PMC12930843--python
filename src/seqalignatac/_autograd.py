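"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's networks need: dense matmul,
sparse-constant @ dense propagation, broadcast add/mul, ReLU, batch
normalization, gradient reversal, concatenation, and fused
binary-cross-entropy / softmax-cross-entropy losses. Gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Adam", "relu", "matmul", "spmm", "concat", "grl",
           "batch_norm", "bce_with_logits", "softmax_cross_entropy"]


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if parent.requires_grad or parent._backward is not None:
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__
    __rmul__ = __mul__


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum gradient over axes that were broadcast in the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        return ((x, g * mask),)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def bwd(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return Tensor(out, parents=(a, b), backward=bwd)


def spmm(A, x: Tensor) -> Tensor:
    """Constant sparse (or dense) matrix times tensor; A carries no gradient."""
    out = A @ x.data

    def bwd(g):
        At = A.T if sp.issparse(A) else np.asarray(A).T
        return ((x, At @ g),)

    return Tensor(out, parents=(x,), backward=bwd)


def concat(tensors, axis=0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        pieces = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            pieces.append((t, g[tuple(idx)]))
        return tuple(pieces)

    return Tensor(out, parents=tuple(tensors), backward=bwd)


def grl(x: Tensor, gamma: float) -> Tensor:
    """Gradient reversal layer: identity forward, -gamma-scaled gradient backward."""
    gamma = float(gamma)
    if gamma < 0:
        raise ValueError("grl coefficient must be >= 0")

    def bwd(g):
        return ((x, -gamma * g),)

    return Tensor(x.data, parents=(x,), backward=bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-feature batch normalization over axis 0.

    In training mode normalizes by batch statistics and updates
    ``running_mean``/``running_var`` in place (biased variance). In eval mode
    uses the running statistics.
    """
    if training:
        mu = x.data.mean(axis=0)
        var = x.data.var(axis=0)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    out = gamma.data * xhat + beta.data
    n = x.data.shape[0]

    def bwd(g):
        dgamma = (g * xhat).sum(axis=0)
        dbeta = g.sum(axis=0)
        dxhat = g * gamma.data
        if training:
            dx = (inv_std / n) * (n * dxhat - dxhat.sum(axis=0)
                                  - xhat * (dxhat * xhat).sum(axis=0))
        else:
            dx = dxhat * inv_std
        return ((x, dx), (gamma, dgamma), (beta, dbeta))

    return Tensor(out, parents=(x, gamma, beta), backward=bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against binary targets.

    Computed in the numerically safe form
    max(z,0) - z*y + log(1 + exp(-|z|)).
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    if z.shape != y.shape:
        raise ValueError(f"logits shape {z.shape} != targets shape {y.shape}")
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = loss.mean()
    n = z.size

    def bwd(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        return ((logits, g * (sig - y) / n),)

    return Tensor(out, parents=(logits,), backward=bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log softmax probability of the integer class labels."""
    z = logits.data
    labels = np.asarray(labels)
    n, c = z.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("labels out of range")
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    out = -logp[np.arange(n), labels].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        return ((logits, g * p / n),)

    return Tensor(out, parents=(logits,), backward=bwd)


class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
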