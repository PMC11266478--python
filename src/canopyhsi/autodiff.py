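"""A compact reverse-mode automatic differentiation engine over numpy.

The classifier networks in this package are small enough to train on a CPU
with plain numpy, so instead of a heavyweight framework they run on this
tape-based engine: a :class:`Tensor` wraps an ``ndarray``, records its
parents and a backward closure, and :meth:`Tensor.backward` walks the tape
in reverse topological order accumulating vector-Jacobian products.

Supported primitives are exactly what the models need: broadcasting
arithmetic, (batched) matmul, N-dimensional valid/same correlation
("convolution" in the deep-learning sense) implemented with
``sliding_window_view`` + ``tensordot``, reductions, max-pooling by
reduction, softmax/log-softmax, elementwise nonlinearities, reshape /
transpose / concatenate / slicing.  Gradient correctness is pinned down by
finite-difference tests rather than symbolic derivation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concatenate", "conv_nd", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=self.data.dtype)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.dtype == np.float64:  # keep python scalars from promoting float32 graphs
            arr = arr.astype(np.float32)
        return Tensor(arr)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.power(-1.0)

    def power(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def backward(g):
            self._accumulate(_unbroadcast(g * exponent * self.data ** (exponent - 1.0), self.shape))
        out._backward = backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = backward
        return out

    __matmul__ = matmul

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        original = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(original))
        return out

    def transpose(self, axes: tuple) -> "Tensor":
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inverse = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            full[key] = g
            self._accumulate(full)
        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient routed to the first argmax."""
        data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(data, parents=(self,))

        def backward(g):
            expanded = data if keepdims else np.expand_dims(data, axis)
            mask = self.data == expanded
            # spread only to the first maximal entry along the axis
            first = np.cumsum(mask, axis=axis) == 1
            mask = mask & first
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(mask * gg)
        out._backward = backward
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(self,))

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))
        out._backward = backward
        return out


def concatenate(tensors: list, axis: int = 0) -> Tensor:
    parents = tuple(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=parents)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])
    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# N-dimensional correlation (1-D, 2-D and 3-D convolutions share this path)


def _im2col(x: np.ndarray, kshape: tuple) -> tuple[np.ndarray, tuple]:
    """Gather sliding windows into a GEMM-ready matrix.

    x: (N, Cin, *S) -> cols (Cin*prod(K), N*prod(O)).  The (Cin, *K) axes
    lead so the copy walks x in near-contiguous runs (one shifted block
    read per kernel offset), which is much cheaper than an
    output-position-major gather.
    """
    nd = len(kshape)
    windows = sliding_window_view(x, kshape, axis=tuple(range(2, 2 + nd)))
    # (N, Cin, *O, *K) -> (Cin, *K, N, *O)
    order = (1,) + tuple(range(2 + nd, 2 + 2 * nd)) + (0,) + tuple(range(2, 2 + nd))
    windows = windows.transpose(order)
    out_shape = windows.shape[2 + nd:]
    cols = np.ascontiguousarray(windows).reshape(-1, x.shape[0] * int(np.prod(out_shape)))
    return cols, out_shape


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | tuple = 0) -> Tensor:
    """Stride-1 correlation of ``x`` (N, Cin, *spatial) with ``w``
    (Cout, Cin, *kernel), optional zero padding and per-channel bias.

    With ``pad=0`` this is a valid-mode convolution; ``pad`` may be an int
    or one int per spatial axis (used for 'same'-style attention convs).
    The window gather is done once and cached for the weight gradient; the
    input gradient is scattered back with one strided add per kernel
    offset, so no full-correlation copy is ever materialized.
    """
    nd = w.ndim - 2
    kshape = w.shape[2:]
    pads = (pad,) * nd if np.isscalar(pad) else tuple(pad)
    x_data = x.data
    if any(pads):
        width = [(0, 0), (0, 0)] + [(p, p) for p in pads]
        x_data = np.pad(x_data, width)
    for ax in range(nd):
        if x_data.shape[2 + ax] < kshape[ax]:
            raise ValueError(
                f"spatial axis {ax}: input extent {x_data.shape[2 + ax]} smaller than "
                f"kernel {kshape[ax]}")
    n, c_in = x_data.shape[0], x_data.shape[1]
    c_out = w.shape[0]
    cols, out_shape = _im2col(x_data, kshape)        # (Cin*K, N*O)
    w2d = w.data.reshape(c_out, -1)
    y = w2d @ cols                                   # (Cout, N*O)
    y = y.reshape((c_out, n) + out_shape)
    y = np.ascontiguousarray(np.swapaxes(y, 0, 1))   # (N, Cout, *O)
    if b is not None:
        y = y + b.data.reshape((1, -1) + (1,) * nd)
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, parents=parents)

    def backward(g):
        # (N, Cout, *O) -> (Cout, N*O)
        g2d = np.ascontiguousarray(np.swapaxes(g, 0, 1)).reshape(c_out, -1)
        if b is not None and b.requires_grad:
            b._accumulate(g2d.sum(axis=1))
        if w.requires_grad:
            w._accumulate((g2d @ cols.T).reshape(w.shape))
        if x.requires_grad:
            # scatter back: one shifted strided add per kernel offset
            dx_col = (w2d.T @ g2d).reshape((c_in,) + kshape + (n,) + out_shape)
            dx = np.zeros_like(x_data)
            for offset in np.ndindex(*kshape):
                src = dx_col[(slice(None),) + offset]      # (Cin, N, *O)
                target = dx[(slice(None), slice(None)) + tuple(
                    slice(o, o + out_shape[ax]) for ax, o in enumerate(offset))]
                target += np.swapaxes(src, 0, 1)
            if any(pads):  # crop the padding back off
                index = [slice(None), slice(None)] + [
                    slice(p, dx.shape[2 + ax] - p) if p else slice(None)
                    for ax, p in enumerate(pads)]
                dx = dx[tuple(index)]
            x._accumulate(dx)
    out._backward = backward
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` given (N, Z) logits."""
    z = logits.data
    n = z.shape[0]
    shifted = z - z.max(axis=1, keepdims=True)
    log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    loss = -log_probs[np.arange(n), labels].mean()
    out = Tensor(loss, parents=(logits,))

    def backward(g):
        probs = np.exp(log_probs)
        probs[np.arange(n), labels] -= 1.0
        logits._accumulate(g * probs / n)
    out._backward = backward
    return out
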