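"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the dual-view encoder and the contrastive
objectives need: broadcasting arithmetic, matmul, reductions, reshape,
transpose, and the usual pointwise nonlinearities.  Gradients are
accumulated by a topological backward sweep; every `Tensor` wraps a float64
numpy array.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, True, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, True, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor(self.data / other.data, True, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g):
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor(self.data**e, True, (self,), bwd)

    def __matmul__(self, other):
        other = self._lift(other)

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, True, (self, other), bwd)

    @property
    def T(self):
        def bwd(g):
            self._accumulate(g.T)

        return Tensor(self.data.T, True, (self,), bwd)

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), True, (self,), bwd)

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    # -- pointwise nonlinearities ---------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, True, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), True, (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, True, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, True, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, True, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, True, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)

        def bwd(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, neg + alpha))

        return Tensor(out_data, True, (self,), bwd)

    # -- structured helpers ---------------------------------------------

    def masked_softmax(self, mask: np.ndarray, axis: int = -1):
        """Row softmax restricted to ``mask``; all-masked rows give zeros."""
        maskf = mask.astype(float)
        neg = np.where(mask, self.data, -np.inf)
        shift = np.max(neg, axis=axis, keepdims=True)
        shift = np.where(np.isfinite(shift), shift, 0.0)  # constant shift
        # pin masked-out logits to the row shift so exp never overflows there
        pinned = self * Tensor(maskf) + Tensor(
            np.where(mask, 0.0, np.broadcast_to(shift, self.data.shape))
        )
        z = (pinned - Tensor(shift)).exp() * Tensor(maskf)
        denom = z.sum(axis=axis, keepdims=True)
        safe = Tensor((denom.data == 0).astype(float))  # avoid 0/0 on empty rows
        return z / (denom + safe)

    def softmax(self, axis: int = -1):
        shift = Tensor(np.max(self.data, axis=axis, keepdims=True))
        z = (self - shift).exp()
        return z / z.sum(axis=axis, keepdims=True)

    def logsumexp_rows(self):
        """Row-wise log-sum-exp of a matrix, returned as an (n,) tensor."""
        shift = Tensor(np.max(self.data, axis=1, keepdims=True))
        z = (self - shift).exp().sum(axis=1)
        return z.log() + shift.reshape(-1)

    def item(self) -> float:
        return float(self.data)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
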