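"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a full-graph variational graph autoencoder:
broadcast-aware arithmetic, matmul, the activations used by GCN/GAT layers,
and a masked row softmax for attention coefficients. Gradients are
accumulated by a topologically ordered sweep from the loss.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to `shape` to undo NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self.grad += -g

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return Tensor._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g.T

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        return Tensor._make(self.data[idx], (self,), backward)

    def square(self):
        return self * self

    def sum(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g * np.ones_like(self.data)

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * sign

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self.grad += g * factor

        return Tensor._make(self.data * factor, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * np.where(pos, 1.0, out_data + alpha)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return Tensor._make(out_data, (self,), backward)

    def masked_softmax(self, mask: np.ndarray):
        """Row-wise softmax restricted to True entries of `mask`; masked-out
        positions get probability 0. Rows must have at least one True."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=1).all():
            raise ValueError("masked_softmax: a row has an empty support")
        neg = np.where(mask, self.data, -np.inf)
        shifted = neg - neg.max(axis=1, keepdims=True)
        expd = np.where(mask, np.exp(shifted), 0.0)
        out_data = expd / expd.sum(axis=1, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=1, keepdims=True)
                self.grad += out_data * (g - dot)

        return Tensor._make(out_data, (self,), backward)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    """A leaf tensor tracked by the optimizer."""
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


def glorot(shape: tuple, rng: np.random.Generator) -> Tensor:
    """Glorot/Xavier uniform initialization."""
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], 1)
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list, lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
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
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
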