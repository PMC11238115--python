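"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine purpose-built for the graph-transformer encoder in
this package: float64 tensors, the handful of differentiable primitives the
model needs (broadcasted arithmetic, batched matmul, softmax, gathers for
embedding tables and attention-bias buckets, smooth activations) and an Adam
optimizer. Desk-scale molecules (tens of atoms) keep graphs small enough that
clarity beats micro-optimization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam", "softmax", "gelu",
           "softplus", "sigmoid", "layer_norm", "gather_rows", "bucket_bias"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data**2, other.shape))
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: (g * exponent * self.data**(exponent - 1),)
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self, *axes):
        axes = axes or tuple(range(self.data.ndim))[::-1]
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: (g.transpose(inverse),)
        return out

    @property
    def T(self):
        return self.transpose()

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: (g * 0.5 / out.data,)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: (g * (1.0 - out.data**2),)
        return out

    # -- autodiff driver ------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into ``.grad`` of
        every reachable parameter."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg.copy() if pg.base is not None else pg
            else:  # leaf parameter
                node.grad = g if node.grad is None else node.grad + g

    def item(self) -> float:
        return float(self.data)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# -- functional primitives ---------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)
    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: (g * s * (1.0 - s),)
    return out


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(x))."""
    v = np.logaddexp(0.0, x.data)
    out = Tensor(v, parents=(x,))
    out._backward = lambda g: (g / (1.0 + np.exp(-x.data)),)
    return out


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    c = np.sqrt(2.0 / np.pi)
    inner = c * (x.data + 0.044715 * x.data**3)
    t = np.tanh(inner)
    out = Tensor(0.5 * x.data * (1.0 + t), parents=(x,))

    def backward(g):
        dt = (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * x.data**2)
        return (g * (0.5 * (1.0 + t) + 0.5 * x.data * dt),)
    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def gather_rows(table: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of a 2D table by integer index; gradients accumulate into
    the selected rows (embedding lookup)."""
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(table.data[index], parents=(table,))

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, index, g)
        return (gt,)
    out._backward = backward
    return out


def bucket_bias(table: Tensor, index: np.ndarray) -> Tensor:
    """Per-head attention-bias lookup: ``out[h, i, j] = table[h, index[i, j]]``.

    ``table`` is (heads, n_buckets); ``index`` an (M, M) integer matrix.
    """
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(table.data[:, index], parents=(table,))

    def backward(g):
        gt = np.zeros_like(table.data)
        heads = table.data.shape[0]
        flat_idx = index.ravel()
        for h in range(heads):
            np.add.at(gt[h], flat_idx, g[h].ravel())
        return (gt,)
    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))
    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}
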