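"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the MSSF network needs: broadcast
arithmetic, batched matrix products, reductions, reshapes, softmax,
valid 2-D convolution (via sliding windows) and dropout.  Gradients are
dense float64 arrays; graphs are built eagerly and freed after
``backward``.  The engine is deliberately small — it is not a general
deep-learning framework — and every operation is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "dropout",
    "matmul",
    "relu",
    "sigmoid",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if t.requires_grad:
            t.grad = g if t.grad is None else t.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    # -- conveniences -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            Tensor._accum(self, _unbroadcast(g, self.data.shape))
            Tensor._accum(other, _unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            Tensor._accum(self, -g)

        return Tensor._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            Tensor._accum(self, _unbroadcast(g * other.data, self.data.shape))
            Tensor._accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            Tensor._accum(self, _unbroadcast(g / other.data, self.data.shape))
            Tensor._accum(
                other,
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return Tensor._node(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def bwd(g):
            Tensor._accum(self, g * exponent * self.data ** (exponent - 1))

        return Tensor._node(out_data, (self,), bwd)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            Tensor._accum(self, g * out_data)

        return Tensor._node(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            Tensor._accum(self, g / self.data)

        return Tensor._node(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self**0.5

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                grad = np.broadcast_to(g, self.data.shape)
            Tensor._accum(self, np.ascontiguousarray(grad))

        return Tensor._node(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bwd(g):
            Tensor._accum(self, g.reshape(self.data.shape))

        return Tensor._node(out_data, (self,), bwd)

    def transpose(self, axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g):
            Tensor._accum(self, g.transpose(inv))

        return Tensor._node(out_data, (self,), bwd)

    def swap_last(self):
        """Transpose the last two axes (batched matrix transpose)."""
        out_data = np.swapaxes(self.data, -1, -2)

        def bwd(g):
            Tensor._accum(self, np.swapaxes(g, -1, -2))

        return Tensor._node(out_data, (self,), bwd)

    def narrow(self, start: int, stop: int):
        """Slice along the last axis; the gradient is zero-padded back."""
        out_data = self.data[..., start:stop]

        def bwd(g):
            full = np.zeros_like(self.data)
            full[..., start:stop] = g
            Tensor._accum(self, full)

        return Tensor._node(out_data, (self,), bwd)


# -- free functions ----------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting on leading axes."""
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            Tensor._accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            Tensor._accum(b, _unbroadcast(gb, b.data.shape))

    return Tensor._node(out_data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bwd(g):
        Tensor._accum(x, g * mask)

    return Tensor._node(out_data, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        Tensor._accum(x, g * out_data * (1.0 - out_data))

    return Tensor._node(out_data, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # the constant max shift leaves the gradient unchanged
    shifted = x - x.data.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            Tensor._accum(t, piece)

    return Tensor._node(out_data, tuple(tensors), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when ``training`` is false or p == 0."""
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float64) / (1.0 - p)
    out_data = x.data * mask

    def bwd(g):
        Tensor._accum(x, g * mask)

    return Tensor._node(out_data, (x,), bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid (no padding), stride-1 2-D cross-correlation.

    x: (B, C, H, W); w: (O, C, k, k); b: (O,) → (B, O, H-k+1, W-k+1).
    """
    k = w.data.shape[-1]
    cols = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))
    out_data = np.einsum("bchwkl,ockl->bohw", cols, w.data, optimize=True)
    out_data += b.data[None, :, None, None]

    def bwd(g):
        if b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bchwkl,bohw->ockl", cols, g, optimize=True)
            Tensor._accum(w, gw)
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
            gcols = np.lib.stride_tricks.sliding_window_view(gp, (k, k), axis=(2, 3))
            wf = w.data[:, :, ::-1, ::-1]
            gx = np.einsum("bohwkl,ockl->bchw", gcols, wf, optimize=True)
            Tensor._accum(x, gx)

    return Tensor._node(out_data, (x, w, b), bwd)
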