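"""Cascading pointer network for overlapping triple extraction.

Entities are tagged with the "01" pointer scheme: a start-probability and
an end-probability per character, thresholded to binary labels, then paired
into spans by the principle of proximity (each start takes the nearest end
at or after it). Head entities are tagged first; then, conditioned on each
head's span vector, a separate start/end tagger per relation finds that
relation's tail entities. Because every head is revisited for every
relation, one head span can yield many triples — the single-entity-overlap
case a flat sequence labelling cannot express.

Internal spans are 0-based half-open; pointer labels mark the start
position and the inclusive end position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor
from .nn import autograd as ag
from .nn.layers import Module, _param


@dataclass(frozen=True, order=True)
class Span:
    """Character span: 0-based, half-open [start, end)."""

    start: int
    end: int
    text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @classmethod
    def from_offsets(cls, text: str, start: int, end: int) -> "Span":
        if end > len(text):
            raise ValueError(f"span [{start}, {end}) beyond text length {len(text)}")
        return cls(start, end, text[start:end])

    def validate_against(self, text: str) -> None:
        if self.end > len(text):
            raise ValueError(f"span [{self.start}, {self.end}) beyond text of "
                             f"length {len(text)}")
        if self.text and text[self.start:self.end] != self.text:
            raise ValueError(
                f"span text {self.text!r} != slice "
                f"{text[self.start:self.end]!r} at [{self.start}, {self.end})")


@dataclass(frozen=True, order=True)
class Triple:
    """(head entity, relation, tail entity) with character offsets."""

    head: Span
    relation: str
    tail: Span

    def to_dict(self) -> dict:
        return {
            "head": {"start": self.head.start, "end": self.head.end,
                     "text": self.head.text},
            "relation": self.relation,
            "tail": {"start": self.tail.start, "end": self.tail.end,
                     "text": self.tail.text},
        }


class PointerParams(Module):
    """Affine start/end scorers: one pair for heads, one pair per relation.

    Head scores (per position i): sigmoid(w_start . M2_i + b_start) and the
    end analogue. Tail scores for relation r: the same affine form applied
    to M2_i + v_sub, with relation-specific weights, so each relation's
    outputs depend only on its own parameters.
    """

    def __init__(self, d_h: int, schema: list[str], rng: np.random.Generator):
        if not schema:
            raise ValueError("relation schema must be non-empty")
        if len(set(schema)) != len(schema):
            raise ValueError("relation schema contains duplicates")
        self.schema = list(schema)
        self.d_h = d_h
        scale = 1.0 / np.sqrt(d_h)
        self.head_w = _param(rng, (d_h, 2), scale)          # cols: start, end
        self.head_b = Tensor(np.zeros(2), requires_grad=True)
        r = len(schema)
        self.tail_w_start = _param(rng, (d_h, r), scale)
        self.tail_b_start = Tensor(np.zeros(r), requires_grad=True)
        self.tail_w_end = _param(rng, (d_h, r), scale)
        self.tail_b_end = Tensor(np.zeros(r), requires_grad=True)

    # -- differentiable paths (Tensor in, Tensor out) ---------------------
    def head_logits(self, m2: Tensor) -> Tensor:
        """(n, 2) logits; column 0 = start, column 1 = end."""
        return m2 @ self.head_w + self.head_b

    def tail_logits(self, m2: Tensor, v_sub: Tensor) -> tuple[Tensor, Tensor]:
        """Two (n, R) logit arrays (start, end) conditioned on the subject."""
        cond = m2 + v_sub
        start = cond @ self.tail_w_start + self.tail_b_start
        end = cond @ self.tail_w_end + self.tail_b_end
        return start, end


def head_pointer_probs(m2: np.ndarray, params: PointerParams
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-position head start/end probabilities, each in (0, 1)."""
    m2 = np.asarray(m2, dtype=np.float64)
    if not np.all(np.isfinite(m2)):
        raise ValueError("non-finite encoder states")
    with ag.no_grad():
        logits = params.head_logits(Tensor(m2)).data
    probs = 1.0 / (1.0 + np.exp(-logits))
    return probs[:, 0], probs[:, 1]


def tail_pointer_probs(m2: np.ndarray, v_sub: np.ndarray,
                       params: PointerParams
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-relation tail start/end probabilities given a subject vector."""
    m2 = np.asarray(m2, dtype=np.float64)
    v_sub = np.asarray(v_sub, dtype=np.float64)
    with ag.no_grad():
        start, end = params.tail_logits(Tensor(m2), Tensor(v_sub))
    p_start = 1.0 / (1.0 + np.exp(-start.data))   # (n, R)
    p_end = 1.0 / (1.0 + np.exp(-end.data))
    return {rel: (p_start[:, j], p_end[:, j])
            for j, rel in enumerate(params.schema)}


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """0/1 labels: 1 iff probability strictly exceeds the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities outside [0, 1]")
    return (probs > threshold).astype(np.int8)


def decode_spans_proximity(start_labels: np.ndarray, end_labels: np.ndarray,
                           text: str | None = None) -> list[Span]:
    """Pair each start marker with the nearest end marker at or after it.

    Ends may serve multiple starts; a start with no following end is
    dropped. The end label marks the inclusive last character, so the
    emitted span is [s, e + 1).
    """
    start_labels = np.asarray(start_labels)
    end_labels = np.asarray(end_labels)
    if start_labels.shape != end_labels.shape:
        raise ValueError("start/end label sequences differ in length")
    n = len(start_labels)
    ends = np.flatnonzero(end_labels)
    spans: list[Span] = []
    for s in np.flatnonzero(start_labels):
        nxt = ends[ends >= s]
        if nxt.size == 0:
            continue
        e = int(nxt[0])
        if text is not None:
            spans.append(Span.from_offsets(text, int(s), e + 1))
        else:
            spans.append(Span(int(s), e + 1))
    return spans


def subject_rep(m2: np.ndarray, head: Span) -> np.ndarray:
    """Subject vector: arithmetic mean of encoder states over the head span."""
    m2 = np.asarray(m2, dtype=np.float64)
    if head.end > m2.shape[0]:
        raise ValueError(f"span [{head.start}, {head.end}) beyond sequence "
                         f"length {m2.shape[0]}")
    seg = m2[head.start:head.end]
    if seg.shape[0] == 0:
        raise ValueError("empty span has no subject representation")
    return seg.mean(axis=0)


def extract_triples(sentence: str, m2: np.ndarray, params: PointerParams,
                    threshold: float = 0.5,
                    schema: list[str] | None = None) -> set[Triple]:
    """Full cascade: decode heads, then per-head per-relation tails.

    Every decoded head is revisited for every relation in the schema, so a
    single head span may appear in many emitted triples. The result is a
    set, hence duplicate-free.
    """
    if schema is not None and list(schema) != params.schema:
        raise ValueError("schema does not match pointer parameters")
    p_start, p_end = head_pointer_probs(m2, params)
    heads = decode_spans_proximity(binarize(p_start, threshold),
                                   binarize(p_end, threshold), sentence)
    triples: set[Triple] = set()
    for head in heads:
        v_sub = subject_rep(m2, head)
        per_rel = tail_pointer_probs(m2, v_sub, params)
        for rel, (ts, te) in per_rel.items():
            tails = decode_spans_proximity(binarize(ts, threshold),
                                           binarize(te, threshold), sentence)
            for tail in tails:
                triples.add(Triple(head=head, relation=rel, tail=tail))
    return triples
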