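"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists for two reasons: the hybrid CNN-LSTM is small enough that
numpy on one CPU trains it comfortably, and guided backpropagation requires
replacing the ReLU gradient rule network-wide, which is trivial when we own
the tape.  Only the operations the yield model needs are implemented:
dense/conv1d/average-pooling layers, LSTM gate arithmetic, and elementwise
nonlinearities.

Gradients accumulate on ``Tensor.grad`` after :meth:`Tensor.backward`.  The
:func:`guided_gradients` context manager switches every ReLU on the tape to
the guided rule (zero the gradient where the forward input was non-positive
*and* where the incoming gradient is negative).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "guided_gradients",
    "add",
    "sub",
    "mul",
    "div",
    "matmul",
    "relu",
    "sigmoid",
    "tanh",
    "sqrt",
    "square",
    "conv1d",
    "avg_pool1d",
    "concat",
    "reshape",
    "index",
    "mean",
    "sum_",
]

_GUIDED = False


@contextlib.contextmanager
def guided_gradients():
    """Within this context, backward passes use the guided-backprop ReLU rule."""
    global _GUIDED
    prev = _GUIDED
    _GUIDED = True
    try:
        yield
    finally:
        _GUIDED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node on the tape: a value, an optional gradient, and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; seeds with ones if ``grad`` omitted."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return index(self, key)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=requires_grad)


def parameter(data) -> Tensor:
    return tensor(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad], backward=backward if req else None)


# -- arithmetic ---------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def square(a: Tensor) -> Tensor:
    return mul(a, a)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


# -- nonlinearities -----------------------------------------------------


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        if _GUIDED:
            a._accumulate(g * mask * (g > 0))
        else:
            a._accumulate(g * mask)

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data**2))

    return _make(out_data, (a,), backward)


# -- shape ops ----------------------------------------------------------


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def _is_basic_key(key) -> bool:
    parts = key if isinstance(key, tuple) else (key,)
    return all(isinstance(p, (int, np.integer, slice)) or p is Ellipsis for p in parts)


def index(a: Tensor, key) -> Tensor:
    out_data = a.data[key]
    basic = _is_basic_key(key)

    def backward(g):
        full = np.zeros_like(a.data)
        if basic:  # basic indexing never aliases, so += is safe and fast
            full[key] += g
        else:
            np.add.at(full, key, g)
        a._accumulate(full)

    return _make(out_data, (a,), backward)


# -- reductions ---------------------------------------------------------


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(out_data, (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), tensor(1.0 / n))


# -- neural-network primitives -----------------------------------------


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1-D convolution with 'same' zero padding.

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    Returns (B, C_out, L).  K must be odd so the padding is symmetric.
    """
    B, C_in, L = x.shape
    C_out, C_in_w, K = w.shape
    if C_in != C_in_w:
        raise ValueError(f"conv1d channel mismatch: input {C_in}, weight {C_in_w}")
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel size for 'same' padding")
    pad = K // 2
    xpad = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xpad, K, axis=2)  # (B,C,L,K)
    # im2col: one dgemm instead of many tiny contractions
    xcol = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(B * L, C_in * K)
    wmat = w.data.reshape(C_out, C_in * K)
    out_data = (xcol @ wmat.T).reshape(B, L, C_out).transpose(0, 2, 1)
    if b is not None:
        out_data = out_data + b.data[None, :, None]

    def backward(g):
        gcol = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * L, C_out)
        if w.requires_grad:
            w._accumulate((gcol.T @ xcol).reshape(C_out, C_in, K))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx_col = (gcol @ wmat).reshape(B, L, C_in, K)
            gx_pad = np.zeros_like(xpad)
            for k in range(K):
                gx_pad[:, :, k : k + L] += gx_col[:, :, :, k].transpose(0, 2, 1)
            x._accumulate(gx_pad[:, :, pad : pad + L])

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out_data, parents, backward)


def lstm_cell(
    x: Tensor, h: Tensor, c: Tensor, wx: Tensor, wh: Tensor, b: Tensor
) -> tuple[Tensor, Tensor]:
    """One fused LSTM step: gates ordered (input, forget, cell, output).

    ``x``: (B, D); ``h``/``c``: (B, H); ``wx``: (D, 4H); ``wh``: (H, 4H);
    ``b``: (4H,).  Returns (h_new, c_new).  The backward pass is
    hand-derived; splitting it between the two outputs is exact because the
    gradient is linear in (dh_new, dc_new).
    """
    H = wh.shape[0]
    z = x.data @ wx.data + h.data @ wh.data + b.data
    i = 1.0 / (1.0 + np.exp(-z[:, 0 * H : 1 * H]))
    f = 1.0 / (1.0 + np.exp(-z[:, 1 * H : 2 * H]))
    g = np.tanh(z[:, 2 * H : 3 * H])
    o = 1.0 / (1.0 + np.exp(-z[:, 3 * H : 4 * H]))
    c_new_data = f * c.data + i * g
    tc = np.tanh(c_new_data)
    h_new_data = o * tc

    def _propagate(dh, dc):
        dc_total = dc + dh * o * (1.0 - tc * tc) if dh is not None else dc
        if dc_total is None:
            return
        dz = np.empty_like(z)
        dz[:, 0 * H : 1 * H] = dc_total * g * i * (1.0 - i)
        dz[:, 1 * H : 2 * H] = dc_total * c.data * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dc_total * i * (1.0 - g * g)
        if dh is not None:
            dz[:, 3 * H : 4 * H] = dh * tc * o * (1.0 - o)
        else:
            dz[:, 3 * H : 4 * H] = 0.0
        if x.requires_grad:
            x._accumulate(dz @ wx.data.T)
        if h.requires_grad:
            h._accumulate(dz @ wh.data.T)
        if c.requires_grad:
            c._accumulate(dc_total * f)
        if wx.requires_grad:
            wx._accumulate(x.data.T @ dz)
        if wh.requires_grad:
            wh._accumulate(h.data.T @ dz)
        if b.requires_grad:
            b._accumulate(dz.sum(axis=0))

    parents = (x, h, c, wx, wh, b)
    h_new = _make(h_new_data, parents, lambda dh: _propagate(dh, np.zeros_like(dh)))
    c_new = _make(c_new_data, parents, lambda dc: _propagate(None, dc))
    return h_new, c_new


def avg_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Average pooling along the last axis; a trailing remainder is dropped."""
    B, C, L = x.shape
    L_out = (L - kernel) // stride + 1
    if stride == kernel:
        used = x.data[:, :, : L_out * kernel]
        out_data = used.reshape(B, C, L_out, kernel).mean(axis=-1)

        def backward(g):
            gx = np.zeros_like(x.data)
            gx[:, :, : L_out * kernel] = np.repeat(g / kernel, kernel, axis=-1)
            x._accumulate(gx)

    else:
        idx = np.arange(L_out) * stride
        out_data = np.stack(
            [x.data[:, :, idx + j] for j in range(kernel)], axis=-1
        ).mean(axis=-1)

        def backward(g):
            gx = np.zeros_like(x.data)
            for j in range(kernel):
                gx[:, :, idx + j] += g / kernel
            x._accumulate(gx)

    return _make(out_data, (x,), backward)
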