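"""Neural layers built on the autograd engine.

Shapes follow the per-sentence convention used throughout the package:
sequences are (n, d) arrays with no batch axis. Weight initialisation is
drawn from a caller-supplied ``numpy.random.Generator`` so a model is
bitwise-reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _param(rng: np.random.Generator, shape, scale: float) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = _param(rng, (d_in, d_out), scale=1.0 / np.sqrt(d_in))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.weight = _param(rng, (n_vocab, dim), scale=scale)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, self.eps)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads != 0:
            raise ValueError(f"hidden dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, dim = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (n, d) -> (h, n, dh)
            return ag.transpose(t.reshape(n, h, dh), (1, 0, 2))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ ag.transpose(k, (0, 2, 1))) * (1.0 / np.sqrt(dh))
        attn = ag.softmax(scores, axis=-1)
        ctx = ag.transpose(attn @ v, (1, 0, 2)).reshape(n, dim)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm Transformer block: LN(x + MHA(x)), then LN(x + FFN(x))."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.attn(x))
        return self.ln2(x + self.ff2(ag.gelu(self.ff1(x))))


class LSTM(Module):
    """Single-direction LSTM exposing the fused sequence primitive."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.wx = _param(rng, (d_in, 4 * d_hidden), scale=1.0 / np.sqrt(d_in))
        self.wh = _param(rng, (d_hidden, 4 * d_hidden), scale=1.0 / np.sqrt(d_hidden))
        self.bias = Tensor(np.zeros(4 * d_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.lstm_fused(x, self.wx, self.wh, self.bias)


class BiLSTM(Module):
    """Forward and backward LSTM passes concatenated per position.

    Each direction has hidden size ``d_out // 2`` so the output keeps the
    input width — required because the subject vector is later added to
    these states elementwise.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        if d_out % 2 != 0:
            raise ValueError("BiLSTM output width must be even")
        self.fwd = LSTM(d_in, d_out // 2, rng)
        self.bwd = LSTM(d_in, d_out // 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h_fwd = self.fwd(x)
        h_bwd = ag.flip(self.bwd(ag.flip(x, axis=0)), axis=0)
        return ag.concat([h_fwd, h_bwd], axis=1)
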