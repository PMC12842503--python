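"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package (Vision-Transformer encoder/decoder, gated
recurrent k-space sweeps, convolutional fusion, UNet baseline) are small
enough to train on a CPU, so the engine favours clarity over kernel-level
speed: every differentiable quantity is a :class:`Tensor` wrapping a float64
ndarray, and ``backward`` walks the recorded graph in reverse topological
order accumulating gradients.

Only the primitives the models need are provided: broadcasting arithmetic,
(batched) matmul, reshape/transpose/slicing/concat, reductions, the usual
pointwise nonlinearities, a numerically-stable softmax, and an ``unfold``
op (im2col) from which 2-D convolution and pooling are composed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad", "default_dtype", "get_default_dtype"]

_DTYPE_STACK: list = [np.float64]


class default_dtype:
    """Context manager selecting the dtype newly created tensors use.

    Float64 (the default) is used for all oracle-grade numerics; the
    training harness switches to float32, which halves memory traffic.
    """

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        _DTYPE_STACK.append(self.dtype)
        return self

    def __exit__(self, *exc):
        _DTYPE_STACK.pop()
        return False


def get_default_dtype():
    return _DTYPE_STACK[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class _NoGrad:
    _depth = 0

    def __enter__(self):
        _NoGrad._depth += 1
        return self

    def __exit__(self, *exc):
        _NoGrad._depth -= 1
        return False

    @staticmethod
    def active() -> bool:
        return _NoGrad._depth > 0


def no_grad() -> _NoGrad:
    """Context manager disabling graph recording (evaluation mode)."""
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=get_default_dtype())
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad.active() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), lambda g: _pair(self, other, backward(g)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._node(out_data, (self, other), lambda g: _pair(self, other, backward(g)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return Tensor._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else a * g
            elif a.ndim == 1:
                ga = g @ b.swapaxes(-1, -2)
                gb = np.outer(a, g)
            else:
                ga = g @ b.swapaxes(-1, -2)
                if b.ndim == 2 and a.ndim > 2:
                    # stacked-input x 2-D weight: one flattened GEMM instead of
                    # a batched product followed by an axis reduction
                    gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                else:
                    gb = a.swapaxes(-1, -2) @ g
            return (
                _unbroadcast(ga, a.shape),
                _unbroadcast(gb, b.shape),
            )

        return Tensor._node(out_data, (self, other), lambda g: _pair(self, other, backward(g)))

    # -- pointwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: ((self, g / self.data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._node(out_data, (self,), lambda g: ((self, g * (1.0 - out_data ** 2)),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._node(out_data, (self,), lambda g: ((self, g * out_data * (1.0 - out_data)),))

    def relu(self):
        mask = self.data > 0
        return Tensor._node(self.data * mask, (self,), lambda g: ((self, g * mask),))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._node(np.abs(self.data), (self,), lambda g: ((self, g * sign),))

    def sqrt(self):
        return self ** 0.5

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation -------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape
        return Tensor._node(out_data, (self,), lambda g: ((self, g.reshape(src_shape)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)
        return Tensor._node(out_data, (self,), lambda g: ((self, g.transpose(inv)),))

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.data.shape

        def backward(g):
            full = np.zeros(src_shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            return ((self, full),)

        return Tensor._node(out_data, (self,), backward)

    def unfold2d(self, ksize: int, stride: int = 1):
        """Extract sliding kxk patches from [..., H, W, C] -> [..., Ho, Wo, k*k*C].

        The channel-last layout keeps the subsequent matmul with a
        [k*k*C, C_out] weight a plain inner product (im2col convolution).
        """
        k = ksize
        x = self.data
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(-3, -2))
        # win: [..., Ho, Wo, C, k, k] -> [..., Ho, Wo, k, k, C]
        win = win[..., ::stride, ::stride, :, :, :]
        win = np.moveaxis(win, -3, -1)
        out_shape = win.shape[:-3] + (k * k * x.shape[-1],)
        out_data = np.ascontiguousarray(win).reshape(out_shape)
        src_shape = x.shape

        def backward(g):
            *lead, Ho, Wo, _ = g.shape
            C = src_shape[-1]
            gw = g.reshape(*lead, Ho, Wo, k, k, C)
            full = np.zeros(src_shape, dtype=g.dtype)
            for di in range(k):
                for dj in range(k):
                    full[..., di : di + Ho * stride : stride,
                         dj : dj + Wo * stride : stride, :] += gw[..., di, dj, :]
            return ((self, full),)

        return Tensor._node(out_data, (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the two spatial axes of [..., H, W, C]."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 3) + [(pad, pad), (pad, pad), (0, 0)]
        out_data = np.pad(self.data, width)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad), slice(None))
        return Tensor._node(out_data, (self,), lambda g: ((self, g[sl]),))

    # -- composite ----------------------------------------------------------

    def softmax(self, axis: int = -1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant: no grad path
        e = (self - Tensor(shift)).exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward -----------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in node._backward(node.grad):
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=parent.data.dtype)
                else:
                    parent.grad = parent.grad + g
            if node is not self:
                node.grad = None  # free intermediate grads


def _pair(a: Tensor, b: Tensor, grads):
    return ((a, grads[0]), (b, grads[1]))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            if t.requires_grad:
                out.append((t, g[tuple(sl)]))
        return out

    return Tensor._node(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        return [(t, parts[i]) for i, t in enumerate(tensors) if t.requires_grad]

    return Tensor._node(out_data, tuple(tensors), backward)
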