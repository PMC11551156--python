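"""Deep character–word fusion encoding.

The encoder is a character-level Transformer stack of L layers in which
lexicon information is injected once, after layer N (``fusion_layer``): at
every position, attention weights over the position's m candidate-word
vectors are computed with a bilinear form against the character state,

    a_i   = softmax(z_i W_attn C_i^T)
    c~_i  = sum_j a_ij c_ij
    h~_i  = z_i + c~_i

and the weighted word vector is added to the character state. The fused
states then pass through the remaining L - N layers, giving the deep
fusion representation M1. Setting N = L degenerates to shallow fusion
(encode fully, fuse once at the top). A BiLSTM over M1 — one forward and
one backward pass of width d_h/2 each, concatenated — yields the
bidirectional semantic representation M2 consumed by the pointer network.

Word vectors (width ``word_dim``) are mapped to the hidden width by a
learned linear projection before scoring; PAD candidate slots carry the
zero vector and by default participate in the softmax unmasked (set
``mask_pad`` to exclude them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .lexicon import CharWordMatches
from .nn import Tensor
from .nn import autograd as ag
from .nn.layers import (BiLSTM, Embedding, LayerNorm, Linear, Module,
                        TransformerEncoderLayer, _param)

UNK_ID = 0  #: embedding row for characters unseen at vocabulary build time


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    Desk-scale defaults; :meth:`full_scale_preset` gives the full-scale
    configuration (12 layers of width 768, fusion after layer 1, m = 3,
    200-dim word vectors, 256-character sentences).
    """

    layers: int = 2
    fusion_layer: int = 1
    hidden_dim: int = 64
    word_dim: int = 200
    m: int = 3
    heads: int = 4
    max_len: int = 160
    ff_dim: int | None = None
    use_fusion: bool = True
    use_bilstm: bool = True
    mask_pad: bool = False
    max_word_len: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if not (1 <= self.fusion_layer <= self.layers):
            raise ValueError(
                f"fusion_layer must lie in [1, {self.layers}], got {self.fusion_layer}")
        if self.hidden_dim % self.heads != 0:
            raise ValueError("hidden_dim must be divisible by heads")
        if self.hidden_dim % 2 != 0:
            raise ValueError("hidden_dim must be even (bidirectional split)")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.ff_dim is None:
            self.ff_dim = 2 * self.hidden_dim

    @classmethod
    def full_scale_preset(cls, **overrides) -> "EncoderConfig":
        base = dict(layers=12, fusion_layer=1, hidden_dim=768, word_dim=200,
                    m=3, heads=12, max_len=256, use_bilstm=True)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class CharVocab:
    """Character → embedding-id map; id 0 is reserved for unknowns."""

    char_to_id: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, texts: list[str]) -> "CharVocab":
        chars = sorted({c for t in texts for c in t})
        return cls(char_to_id={c: i + 1 for i, c in enumerate(chars)})

    def __len__(self) -> int:
        return len(self.char_to_id) + 1

    def encode(self, text: str) -> np.ndarray:
        return np.array([self.char_to_id.get(c, UNK_ID) for c in text],
                        dtype=np.intp)

    def to_dict(self) -> dict:
        return dict(self.char_to_id)

    @classmethod
    def from_dict(cls, d: dict) -> "CharVocab":
        return cls(char_to_id={str(k): int(v) for k, v in d.items()})


class FusionParams(Module):
    """Bilinear attention matrix and the word-to-hidden projection."""

    def __init__(self, d_h: int, d_w: int, rng: np.random.Generator):
        self.w_attn = _param(rng, (d_h, d_h), scale=1.0 / np.sqrt(d_h))
        self.word_projection = Linear(d_w, d_h, rng)


def word_attention_fuse(char_vec: np.ndarray, candidate_vecs: np.ndarray,
                        w_attn: np.ndarray, pad_mask: np.ndarray | None = None,
                        mask_pad: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Single-position fusion (numpy reference path).

    ``char_vec``: (d_h,); ``candidate_vecs``: (m, d_h) already projected to
    the hidden width; ``w_attn``: (d_h, d_h). Returns the fused vector
    ``char_vec + sum_j a_j c_j`` and the attention weights ``a``.
    """
    z = np.asarray(char_vec, dtype=np.float64)
    c = np.asarray(candidate_vecs, dtype=np.float64)
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(c))):
        raise ValueError("non-finite fusion inputs")
    logits = z @ np.asarray(w_attn) @ c.T
    if mask_pad and pad_mask is not None:
        logits = np.where(pad_mask, -1e9, logits)
    shifted = logits - logits.max()
    e = np.exp(shifted)
    weights = e / e.sum()
    fused = z + weights @ c
    return fused, weights


class DCWFEncoder(Module):
    """Character embedding → Transformer stack with one fusion point → M1,
    then an optional BiLSTM → M2.

    All weights are drawn from ``default_rng(config.seed)`` at
    construction, so two encoders with the same config and vocabulary are
    bitwise identical.
    """

    def __init__(self, config: EncoderConfig, vocab: CharVocab):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dim
        self.char_emb = Embedding(len(vocab), d, rng)
        self.pos_emb = Embedding(config.max_len, d, rng)
        self.emb_norm = LayerNorm(d)
        self.layers = [TransformerEncoderLayer(d, config.heads, config.ff_dim, rng)
                       for _ in range(config.layers)]
        self.fusion = FusionParams(d, config.word_dim, rng)
        self.bilstm = BiLSTM(d, d, rng)

    # -- pieces -----------------------------------------------------------
    def embed(self, sentence: str) -> Tensor:
        if not sentence:
            raise ValueError("cannot encode an empty sentence")
        sentence = sentence[:self.config.max_len]
        ids = self.vocab.encode(sentence)
        n = len(ids)
        x = self.char_emb(ids) + self.pos_emb(np.arange(n))
        return self.emb_norm(x)

    def fuse_states(self, x: Tensor, matches: CharWordMatches) -> Tensor:
        """Attention-fuse candidate-word vectors into every position of x."""
        n, d = x.shape
        if len(matches) != n:
            raise ValueError(f"matches cover {len(matches)} positions, states {n}")
        m = matches.m
        c_raw = matches.vectors()                     # (n, m, d_w)
        proj = self.fusion.word_projection(
            Tensor(c_raw.reshape(n * m, -1))).reshape(n, m, d)
        zw = (x @ self.fusion.w_attn).reshape(n, 1, d)
        logits = (zw @ ag.transpose(proj, (0, 2, 1))).reshape(n, m)
        if self.config.mask_pad:
            logits = logits + np.where(matches.pad_mask(), -1e9, 0.0)
        weights = ag.softmax(logits, axis=-1)
        fused = (weights.reshape(n, 1, m) @ proj).reshape(n, d)
        return x + fused

    def bilstm_forward(self, m1: Tensor) -> Tensor:
        """M1 → M2; identity when the bidirectional layer is ablated."""
        if not self.config.use_bilstm:
            return m1
        return self.bilstm(m1)

    # -- full forward ------------------------------------------------------
    def dcwfe_forward(self, sentence: str, matches: CharWordMatches) -> Tensor:
        """Deep character–word fusion representation M1, shape (n, d_h)."""
        x = self.embed(sentence)
        n = x.shape[0]
        matches = matches.truncated(n)
        for idx, layer in enumerate(self.layers, start=1):
            x = layer(x)
            if idx == self.config.fusion_layer and self.config.use_fusion:
                x = self.fuse_states(x, matches)
        return x

    def forward(self, sentence: str,
                matches: CharWordMatches) -> tuple[Tensor, Tensor]:
        m1 = self.dcwfe_forward(sentence, matches)
        m2 = self.bilstm_forward(m1)
        return m1, m2

    def encode(self, sentence: str,
               matches: CharWordMatches) -> tuple[np.ndarray, np.ndarray]:
        """Inference path: (M1, M2) as plain arrays, no tape."""
        with ag.no_grad():
            m1, m2 = self.forward(sentence, matches)
        return m1.data, m2.data


@dataclass
class EncodedText:
    """Encoder output for one (possibly truncated) sentence."""

    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        if self.m1.shape != self.m2.shape:
            raise ValueError("M1 and M2 must have identical shapes")
        if not (np.all(np.isfinite(self.m1)) and np.all(np.isfinite(self.m2))):
            raise ValueError("non-finite encoder output")

    @property
    def n(self) -> int:
        return self.m1.shape[0]
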