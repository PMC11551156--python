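"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers the parents and the vector-Jacobian product that produced it.
``Tensor.backward()`` runs the closures in reverse topological order.

Only the operations the extraction model needs are provided; recurrent
layers use a fused LSTM primitive (:func:`lstm_fused`) with a hand-written
backward pass so the per-timestep loop does not inflate the tape.
All arithmetic is float64.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
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
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[np.ndarray], None] | None = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              vjp: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = parents
            out._vjp = vjp
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul(self, 1.0 / other)
        return mul(self, power(_as_tensor(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitives


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def vjp(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor._make(out_data, (a, b), vjp)


def mul(a, b) -> Tensor:
    if np.isscalar(b):
        a = _as_tensor(a)
        out_data = a.data * b

        def vjp_s(g):
            if a.requires_grad:
                a._accumulate(g * b)

        return Tensor._make(out_data, (a,), vjp_s)
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def vjp(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), vjp)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def vjp(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), vjp)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** exponent

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1))

    return Tensor._make(out_data, (a,), vjp)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return Tensor._make(out_data, (a,), vjp)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return Tensor._make(out_data, (a,), vjp)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.tanh(a.data)

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out_data ** 2))

    return Tensor._make(out_data, (a,), vjp)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = _sigmoid_np(a.data)

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (a,), vjp)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    # overflow-free: sigma(x) = (tanh(x/2) + 1) / 2
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor._make(out_data, (a,), vjp)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a) -> Tensor:
    """tanh-approximated GELU (the usual Transformer feed-forward nonlinearity)."""
    a = _as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def vjp(g):
        if a.requires_grad:
            dinner = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
            da = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            a._accumulate(g * da)

    return Tensor._make(out_data, (a,), vjp)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if a.requires_grad:
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g2, a.data.shape).copy())

    return Tensor._make(out_data, (a,), vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[i] for i in axis]))
    else:
        n = a.data.shape[axis]
    return tsum(a, axis, keepdims) * (1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)
    orig = a.data.shape

    def vjp(g):
        if a.requires_grad:
            a._accumulate(g.reshape(orig))

    return Tensor._make(out_data, (a,), vjp)


def transpose(a, axes=None) -> Tensor:
    a = _as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = None if axes is None else np.argsort(axes)

    def vjp(g):
        if a.requires_grad:
            a._accumulate(np.transpose(g, inv))

    return Tensor._make(out_data, (a,), vjp)


def take(a, idx) -> Tensor:
    """Indexing/slicing; integer-array gather backed by ``np.add.at``."""
    a = _as_tensor(a)
    out_data = a.data[idx]

    def vjp(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accumulate(ga)

    return Tensor._make(out_data, (a,), vjp)


def flip(a, axis=0) -> Tensor:
    a = _as_tensor(a)
    out_data = np.flip(a.data, axis=axis)

    def vjp(g):
        if a.requires_grad:
            a._accumulate(np.flip(g, axis=axis))

    return Tensor._make(out_data, (a,), vjp)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, vjp)


def softmax(a, axis=-1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return Tensor._make(out_data, (a,), vjp)


def layer_norm(a, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis (fused forward/backward)."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    d = x.shape[-1]

    def vjp(g):
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if a.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) \
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(term * inv)

    return Tensor._make(out_data, (a, gamma, beta), vjp)


def bce_with_logits(logits, targets, pos_weight: float = 1.0) -> Tensor:
    """Elementwise binary cross-entropy from logits (numerically stable).

    ``pos_weight`` multiplies the loss at positive targets, countering the
    extreme label sparsity of pointer tagging.
    """
    logits = _as_tensor(logits)
    t = np.asarray(targets, dtype=np.float64)
    x = logits.data
    # max(x,0) - x*t + log(1 + exp(-|x|))
    out_data = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    p = _sigmoid_np(x)
    if pos_weight != 1.0:
        w = 1.0 + (pos_weight - 1.0) * t
        out_data = out_data * w
    else:
        w = None

    def vjp(g):
        if logits.requires_grad:
            delta = p - t
            if w is not None:
                delta = delta * w
            logits._accumulate(g * delta)

    return Tensor._make(out_data, (logits,), vjp)


def lstm_fused(x, wx, wh, b) -> Tensor:
    """Unidirectional LSTM over a sequence, as one tape node.

    ``x``: (n, D); ``wx``: (D, 4H); ``wh``: (H, 4H); ``b``: (4H,).
    Gate order along the last axis is [input, forget, cell, output].
    Initial hidden and cell states are zero. Returns the (n, H) hidden
    sequence. The per-timestep recurrence runs inside this primitive so
    the backward loop is hand-written rather than taped.
    """
    x, wx, wh, b = map(_as_tensor, (x, wx, wh, b))
    n, _ = x.data.shape
    h_dim = wh.data.shape[0]
    wh_d = wh.data
    pre = x.data @ wx.data + b.data          # (n, 4H), input contribution
    hs = np.zeros((n, h_dim))
    # per-step caches, preallocated so the loop stays allocation-light
    sig = np.zeros((n, 4 * h_dim))           # sigma(a) for i/f/o; g in gs
    gs = np.zeros((n, h_dim))
    cs = np.zeros((n, h_dim))
    tcs = np.zeros((n, h_dim))
    h_prev = np.zeros(h_dim)
    c_prev = np.zeros(h_dim)
    for t in range(n):
        a = pre[t] + h_prev @ wh_d
        s = _sigmoid_np(a)
        sig[t] = s
        g_ = np.tanh(a[2 * h_dim:3 * h_dim])
        gs[t] = g_
        c = s[h_dim:2 * h_dim] * c_prev + s[:h_dim] * g_
        cs[t] = c
        tc = np.tanh(c)
        tcs[t] = tc
        hs[t] = s[3 * h_dim:] * tc
        h_prev, c_prev = hs[t], c

    def vjp(grad_h):
        da_all = np.zeros((n, 4 * h_dim))
        dh_next = np.zeros(h_dim)
        dc_next = np.zeros(h_dim)
        for t in range(n - 1, -1, -1):
            s = sig[t]
            i, f, o = s[:h_dim], s[h_dim:2 * h_dim], s[3 * h_dim:]
            g_, tc = gs[t], tcs[t]
            c_prev_t = cs[t - 1] if t > 0 else np.zeros(h_dim)
            dh = grad_h[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            da = da_all[t]
            da[:h_dim] = dc * g_ * i * (1.0 - i)
            da[h_dim:2 * h_dim] = dc * c_prev_t * f * (1.0 - f)
            da[2 * h_dim:3 * h_dim] = dc * i * (1.0 - g_ ** 2)
            da[3 * h_dim:] = do * o * (1.0 - o)
            dh_next = wh_d @ da
            dc_next = dc * f
        h_prev_all = np.vstack([np.zeros((1, h_dim)), hs[:-1]])
        if x.requires_grad:
            x._accumulate(da_all @ wx.data.T)
        if wx.requires_grad:
            wx._accumulate(x.data.T @ da_all)
        if wh.requires_grad:
            wh._accumulate(h_prev_all.T @ da_all)
        if b.requires_grad:
            b._accumulate(da_all.sum(axis=0))

    return Tensor._make(hs, (x, wx, wh, b), vjp)
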