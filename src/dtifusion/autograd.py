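"""A small reverse-mode automatic differentiation engine on numpy.

Provides exactly the operations the multi-view network needs — broadcast
arithmetic, (batched) matmul, reductions, softmax-friendly primitives,
embedding lookup, window unfolding for 1-D convolution, and a masked
max — together with an Adam optimizer. Tensors record their parents and
a local backward closure; ``Tensor.backward()`` runs a topological sweep
accumulating gradients.

Every operation's gradient is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

Array = np.ndarray

# Computation dtype. float32 is the working default (BLAS throughput,
# memory); switch to float64 for high-precision checks such as the
# finite-difference gradient verification in the test suite.
DTYPE = np.dtype(np.float32)


@contextmanager
def use_dtype(dtype):
    """Temporarily change the dtype newly created tensors use."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        DTYPE = old


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[Array], None] | None = None

    # -- bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Array | None = None) -> None:
        """Reverse sweep from this tensor; ``grad`` defaults to ones."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many layers)
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
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node._accumulate(g)
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if parent.requires_grad or parent._backward is not None:
                        if id(parent) in grads:
                            grads[id(parent)] += pg
                        else:
                            grads[id(parent)] = pg

    # -- arithmetic --------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        out._backward = lambda g: (
            (self, _unbroadcast(g, self.shape)),
            (other, _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: ((self, -g),)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        out._backward = lambda g: (
            (self, _unbroadcast(g * other.data, self.shape)),
            (other, _unbroadcast(g * self.data, other.shape)),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        out._backward = lambda g: ((self, g * p * self.data ** (p - 1.0)),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))

        def backward(g: Array):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            return (self, _unbroadcast(ga, self.shape)), (other, _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- shaping -----------------------------------------------------

    def reshape(self, *shape: int):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda g: ((self, g.reshape(self.shape)),)
        return out

    def transpose(self, *axes: int):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(*axes), (self,))
        out._backward = lambda g: ((self, g.transpose(*inv)),)
        return out

    # -- reductions --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g: Array):
            if axis is None:
                return ((self, np.broadcast_to(g, self.shape).copy()),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = _node(out_data, (self,))

        def backward(g: Array):
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            mask = self.data == expanded
            # split ties evenly so the gradient check stays symmetric
            mask = mask / mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            return ((self, mask * gg),)

        out._backward = backward
        return out


def _node(data: Array, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- nonlinearities ---------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))
    out._backward = lambda g: ((x, g * (x.data > 0)),)
    return out


def sigmoid(x: Tensor) -> Tensor:
    xd = x.data
    s = np.empty_like(xd)
    pos = xd >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-xd[pos]))
    e = np.exp(xd[~pos])
    s[~pos] = e / (1.0 + e)
    out = _node(s, (x,))
    out._backward = lambda g: ((x, g * s * (1.0 - s)),)
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))
    out._backward = lambda g: ((x, g / x.data),)
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = _node(e, (x,))
    out._backward = lambda g: ((x, g * e),)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is zero outside [lo, hi] (straight-through inside)."""
    out = _node(np.clip(x.data, lo, hi), (x,))
    out._backward = lambda g: ((x, g * ((x.data >= lo) & (x.data <= hi))),)
    return out


def softmax(x: Tensor, axis: int = -1, bias: Array | None = None) -> Tensor:
    """Numerically stable softmax along ``axis`` (single fused op).

    ``bias`` is an optional constant added to the logits first (e.g. a
    large-negative padding mask); fusing it here avoids materializing an
    extra logit-sized node. The Jacobian is unchanged by a constant
    shift, so the backward pass is identical.
    """
    z = x.data if bias is None else x.data + np.asarray(bias, dtype=x.data.dtype)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z, out=z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _node(s, (x,))

    def backward(g: Array):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((x, s * (g - dot)),)

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: Array):
        pieces = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, pieces))

    out._backward = backward
    return out


def embedding(table: Tensor, ids: Array) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient to the table."""
    ids = np.asarray(ids)
    out = _node(table.data[ids], (table,))

    def backward(g: Array):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, table.shape[-1]))
        return ((table, gt),)

    out._backward = backward
    return out


def unfold(x: Tensor, kernel: int) -> Tensor:
    """Sliding windows for 1-D convolution.

    (B, L, C) -> (B, L-kernel+1, kernel*C); a convolution is then a
    plain matmul with a (kernel*C, F) weight.
    """
    B, L, C = x.shape
    Lo = L - kernel + 1
    if Lo < 1:
        raise ValueError(f"kernel {kernel} longer than sequence {L}")
    win = np.lib.stride_tricks.sliding_window_view(x.data, kernel, axis=1)
    # win: (B, Lo, C, kernel) -> (B, Lo, kernel, C)
    fwd = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Lo, kernel * C)
    out = _node(fwd, (x,))

    def backward(g: Array):
        gw = g.reshape(B, Lo, kernel, C)
        gx = np.zeros((B, L, C), dtype=g.dtype)
        for k in range(kernel):
            gx[:, k : k + Lo, :] += gw[:, :, k, :]
        return ((x, gx),)

    out._backward = backward
    return out


def add_constant(x: Tensor, c: Array) -> Tensor:
    """Add a non-trainable array (mask bias, positional encoding)."""
    c = np.asarray(c, dtype=x.data.dtype)
    out = _node(x.data + c, (x,))
    out._backward = lambda g: ((x, _unbroadcast(g, x.shape)),)
    return out


def mul_constant(x: Tensor, c: Array) -> Tensor:
    """Multiply by a non-trainable array (dropout / padding masks)."""
    c = np.asarray(c, dtype=x.data.dtype)
    out = _node(x.data * c, (x,))
    out._backward = lambda g: ((x, _unbroadcast(g * c, x.shape)),)
    return out


# -- optimizer --------------------------------------------------------


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
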