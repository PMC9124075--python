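"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records, for each operation, a
closure that propagates the upstream gradient to its parents.  The op set
is exactly what dense convolutional networks with channel attention need:
broadcast arithmetic, matmul, ReLU/sigmoid, reductions, concatenation,
2-D convolution (im2col + BLAS), average/max pooling, and a fused
softmax-cross-entropy loss.  Convolution caches its column matrix only
while gradients are enabled, so inference passes stay lean.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---------------------------------------------------------------- utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward):
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if track:
            return Tensor(data, requires_grad=True, parents=parents, backward=backward)
        return Tensor(data)

    def backward(self, grad=None):
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # release the graph: drop closures (and their cached buffers) and
        # parent links so memory is reclaimed promptly after each step
        for node in topo:
            node._backward = None
            node._parents = ()

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self.grad += -g

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2, other.data.shape)

        return self._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1)

        return self._make(out_data, (self,), backward)

    def matmul(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ----------------------------------------------------------- activations
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis, keepdims=False):
        """Maximum over ``axis``; ties share the gradient equally."""
        axis = tuple(np.atleast_1d(axis).tolist())
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += mask * (g / counts)

        return self._make(out_data if keepdims else out_data.squeeze(axis), (self,), backward)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(old_shape)

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    tensors = list(tensors)  # snapshot: callers may mutate their list later
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    track = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if track:
        return Tensor(out_data, requires_grad=True, parents=tuple(tensors), backward=backward)
    return Tensor(out_data)


# ------------------------------------------------------------------ conv/pool
def _window_view(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (N, C, Hout, Wout, kh, kw) of sliding windows."""
    N, C, H, W = x.shape
    Hout = (H - kh) // stride + 1
    Wout = (W - kw) // stride + 1
    s = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(N, C, Hout, Wout, kh, kw),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )


def _scatter_windows(dwin: np.ndarray, xshape: tuple, kh: int, kw: int, stride: int) -> np.ndarray:
    """Accumulate per-window gradients (N,C,Hout,Wout,kh,kw) back onto x."""
    N, C, H, W = xshape
    _, _, Hout, Wout = dwin.shape[:4]
    dx = np.zeros(xshape)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * Hout : stride, j : j + stride * Wout : stride] += dwin[
                :, :, :, :, i, j
            ]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,Cin,H,W), weight (Cout,Cin,kh,kw)."""
    Cout, Cin, kh, kw = weight.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    N, _, Hp, Wp = xp.shape
    Hout = (Hp - kh) // stride + 1
    Wout = (Wp - kw) // stride + 1
    win = _window_view(xp, kh, kw, stride)  # (N,Cin,Hout,Wout,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Hout * Wout, Cin * kh * kw
    )
    w2 = weight.data.reshape(Cout, -1)
    out = (cols @ w2.T).reshape(N, Hout, Wout, Cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)
    track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not track:
        return Tensor(out)

    def backward(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(N * Hout * Wout, Cout)
        if weight.requires_grad:
            weight.grad += (g2.T @ cols).reshape(weight.data.shape)
        if bias is not None and bias.requires_grad:
            bias.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad:
            dcols = g2 @ w2  # (N*Hout*Wout, Cin*kh*kw)
            dwin = dcols.reshape(N, Hout, Wout, Cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = _scatter_windows(dwin, xp.shape, kh, kw, stride)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x.grad += dxp

    return Tensor(out, requires_grad=True, parents=parents, backward=backward)


def avg_pool2d(x: Tensor, kernel: int = 2, stride: int | None = None) -> Tensor:
    """Average pooling; trailing rows/columns that do not fill a window are
    dropped (floor semantics)."""
    stride = kernel if stride is None else stride
    win = _window_view(x.data, kernel, kernel, stride)
    out = win.mean(axis=(4, 5))
    N, C, Hout, Wout = out.shape

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.broadcast_to(
            (g / (kernel * kernel))[..., None, None], (N, C, Hout, Wout, kernel, kernel)
        )
        x.grad += _scatter_windows(dwin, x.data.shape, kernel, kernel, stride)

    return Tensor._make(out, (x,), backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 0) -> Tensor:
    """Max pooling with optional padding (padded entries never win)."""
    xp = x.data
    if padding:
        xp = np.pad(
            xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    win = _window_view(xp, kernel, kernel, stride)
    out = win.max(axis=(4, 5))
    mask = win == out[..., None, None]
    counts = mask.sum(axis=(4, 5))

    def backward(g):
        if not x.requires_grad:
            return
        dwin = mask * (g / counts)[..., None, None]
        dxp = _scatter_windows(dwin, xp.shape, kernel, kernel, stride)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x.grad += dxp

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def log_softmax(logits: Tensor) -> Tensor:
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    out = z - lse
    softmax = np.exp(out)

    def backward(g):
        if logits.requires_grad:
            logits.grad += g - softmax * g.sum(axis=1, keepdims=True)

    return Tensor._make(out, (logits,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer class labels."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    ls = log_softmax(logits)
    picked_data = ls.data[np.arange(n), labels]
    loss_data = -picked_data.mean()

    def backward(g):
        if ls.requires_grad:
            dls = np.zeros_like(ls.data)
            dls[np.arange(n), labels] = -g / n
            ls.grad += dls

    return Tensor._make(np.asarray(loss_data), (ls,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain ndarray softmax over the last axis (for inference)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
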