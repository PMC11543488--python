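"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the edge-scoring network needs: dense affine
maps, elementwise nonlinearities, batch statistics, and the three
graph-sparse primitives (row gather, segment sum, segment softmax) that
implement message passing over edge lists.  Arrays are float64 throughout;
every backward rule is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------ infra

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------- arithmetic

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    __matmul__ = matmul

    # ----------------------------------------------------------- elementwise

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # ------------------------------------------------------------ reductions

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping

    def reshape(self, *shape) -> "Tensor":
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(self.shape),)
        )


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Rows ``t[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor._make(t.data[idx], (t,), backward)


def segment_sum(t: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    seg = np.asarray(seg, dtype=np.intp)
    out = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(out, seg, t.data)
    return Tensor._make(out, (t,), lambda g: (g[seg],))


def segment_softmax(logits: Tensor, seg: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of per-row logits within each segment (numerically stable).

    Rows belonging to a segment sum to 1 along axis 0 within that segment.
    Empty segments contribute no rows.
    """
    seg = np.asarray(seg, dtype=np.intp)
    x = logits.data
    mx = np.full((num_segments,) + x.shape[1:], -np.inf)
    np.maximum.at(mx, seg, x)
    ex = np.exp(x - mx[seg])
    denom = np.zeros_like(mx)
    np.add.at(denom, seg, ex)
    out = ex / denom[seg]

    def backward(g):
        dot = np.zeros_like(mx)
        np.add.at(dot, seg, out * g)
        return (out * (g - dot[seg]),)

    return Tensor._make(out, (logits,), backward)


class Adam:
    """Standard Adam with bias correction, over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
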