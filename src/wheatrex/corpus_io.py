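"""Span-annotated corpora: JSONL I/O and the "01" pointer label scheme.

One sentence per JSONL line::

    {"text": "...", "triples": [{"head": {"start": 0, "end": 12, "text": "..."},
                                 "relation": "Unit weight",
                                 "tail": {"start": 14, "end": 21, "text": "..."}}]}

Offsets are 0-based, half-open, and count Unicode characters, not bytes.
A doccano-style export (``entities`` + ``relations`` lists with ids) is
accepted by :func:`from_doccano_record`.

Label conversion follows the pointer scheme: the first character of a span
gets a 1 in the start sequence and the last character a 1 in the end
sequence; everything else is 0. Head labels pool all gold head spans of a
sentence; tail labels are kept per (gold head, relation), the unit the
cascade is supervised on. Spans sharing a boundary share the same 1 — the
scheme is inherently shared, so decoding such conflicting gold is
ambiguous (documented, not patched).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extractor import Span, Triple, decode_spans_proximity


class CorpusValidationError(ValueError):
    """Annotation inconsistent with its text or schema; names the line."""


@dataclass
class AnnotatedSentence:
    text: str
    triples: list[Triple] = field(default_factory=list)

    def validate(self, schema: list[str] | None = None) -> None:
        for t in self.triples:
            t.head.validate_against(self.text)
            t.tail.validate_against(self.text)
            if schema is not None and t.relation not in schema:
                raise ValueError(f"unknown relation {t.relation!r}")

    def head_spans(self) -> list[Span]:
        """Distinct gold head spans, in order of first appearance."""
        seen: dict[tuple[int, int], Span] = {}
        for t in self.triples:
            seen.setdefault((t.head.start, t.head.end), t.head)
        return list(seen.values())

    def tails_of(self, head: Span, relation: str) -> list[Span]:
        return [t.tail for t in self.triples
                if (t.head.start, t.head.end) == (head.start, head.end)
                and t.relation == relation]

    def to_dict(self) -> dict:
        return {"text": self.text, "triples": [t.to_dict() for t in self.triples]}

    @classmethod
    def from_dict(cls, obj: dict) -> "AnnotatedSentence":
        text = obj["text"]

        def span(d: dict) -> Span:
            s = Span(int(d["start"]), int(d["end"]), d.get("text", ""))
            s.validate_against(text)
            if not s.text:
                s = Span.from_offsets(text, s.start, s.end)
            return s

        triples = [Triple(head=span(t["head"]), relation=t["relation"],
                          tail=span(t["tail"])) for t in obj.get("triples", [])]
        return cls(text=text, triples=triples)


def read_jsonl(path: str | Path,
               schema: list[str] | None = None) -> list[AnnotatedSentence]:
    """Read and validate an annotated corpus; errors carry line numbers."""
    sentences: list[AnnotatedSentence] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                sent = AnnotatedSentence.from_dict(obj)
                sent.validate(schema)
            except (ValueError, KeyError) as exc:
                raise CorpusValidationError(f"{path}: line {lineno}: {exc}") from exc
            sentences.append(sent)
    return sentences


def write_jsonl(sentences: list[AnnotatedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(json.dumps(sent.to_dict(), ensure_ascii=False) + "\n")


def load_schema(path: str | Path) -> list[str]:
    """Relation schema: a JSON list of relation label strings."""
    with open(path, "r", encoding="utf-8") as fh:
        schema = json.load(fh)
    if (not isinstance(schema, list)
            or not all(isinstance(r, str) and r for r in schema)):
        raise ValueError(f"{path}: schema must be a JSON list of non-empty strings")
    if len(set(schema)) != len(schema):
        raise ValueError(f"{path}: schema contains duplicate relations")
    return schema


def save_schema(schema: list[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(list(schema), fh, ensure_ascii=False, indent=1)


def from_doccano_record(obj: dict,
                        relation_types: dict | None = None) -> AnnotatedSentence:
    """Convert one doccano relation-export record.

    Expects ``{"text", "entities": [{"id", "start_offset", "end_offset", ...}],
    "relations": [{"from_id", "to_id", "type"}]}``.
    """
    text = obj["text"]
    ents: dict[int, Span] = {}
    for e in obj.get("entities", []):
        ents[int(e["id"])] = Span.from_offsets(
            text, int(e["start_offset"]), int(e["end_offset"]))
    triples = []
    for r in obj.get("relations", []):
        try:
            head, tail = ents[int(r["from_id"])], ents[int(r["to_id"])]
        except KeyError as exc:
            raise CorpusValidationError(
                f"relation references unknown entity id {exc}") from exc
        triples.append(Triple(head=head, relation=str(r["type"]), tail=tail))
    return AnnotatedSentence(text=text, triples=triples)


def read_doccano_jsonl(path: str | Path) -> list[AnnotatedSentence]:
    sentences = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                sentences.append(from_doccano_record(json.loads(line)))
            except (ValueError, KeyError) as exc:
                raise CorpusValidationError(f"{path}: line {lineno}: {exc}") from exc
    return sentences


# ---------------------------------------------------------------------------
# "01" pointer labels


@dataclass
class PointerLabels:
    """Gold pointer labels for one sentence.

    ``head_start`` / ``head_end``: length-n 0/1 arrays pooling every gold
    head span. ``tails``: for each gold head span (keyed by its (start, end)
    offsets), a pair of (R, n) 0/1 arrays over the relation schema —
    row r marks the tails the head holds under relation ``schema[r]``.
    """

    head_start: np.ndarray
    head_end: np.ndarray
    tails: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    schema: list[str]

    @property
    def n(self) -> int:
        return len(self.head_start)


def _mark(seq_start: np.ndarray, seq_end: np.ndarray, span: Span) -> None:
    seq_start[span.start] = 1
    seq_end[span.end - 1] = 1


def spans_to_labels(sentence: AnnotatedSentence,
                    schema: list[str]) -> PointerLabels:
    """Gold spans → "01" pointer labels (start and inclusive-end marks)."""
    sentence.validate(schema)
    n = len(sentence.text)
    if n == 0:
        raise ValueError("empty sentence has no label positions")
    head_start = np.zeros(n, dtype=np.int8)
    head_end = np.zeros(n, dtype=np.int8)
    rel_index = {r: j for j, r in enumerate(schema)}
    tails: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for head in sentence.head_spans():
        _mark(head_start, head_end, head)
        tails[(head.start, head.end)] = (
            np.zeros((len(schema), n), dtype=np.int8),
            np.zeros((len(schema), n), dtype=np.int8),
        )
    for t in sentence.triples:
        ts, te = tails[(t.head.start, t.head.end)]
        j = rel_index[t.relation]
        ts[j, t.tail.start] = 1
        te[j, t.tail.end - 1] = 1
    return PointerLabels(head_start=head_start, head_end=head_end,
                         tails=tails, schema=list(schema))


def labels_to_spans(labels: PointerLabels, text: str) -> AnnotatedSentence:
    """Inverse of :func:`spans_to_labels` via proximity decoding.

    Exact inversion holds when gold spans do not conflict (no foreign end
    marker strictly inside another span's start→end stretch); the pointer
    scheme cannot distinguish such cases.
    """
    if len(text) != labels.n:
        raise ValueError("label length does not match text length")
    heads = decode_spans_proximity(labels.head_start, labels.head_end, text)
    triples: list[Triple] = []
    for head in heads:
        key = (head.start, head.end)
        if key not in labels.tails:
            continue
        ts, te = labels.tails[key]
        for j, rel in enumerate(labels.schema):
            for tail in decode_spans_proximity(ts[j], te[j], text):
                triples.append(Triple(head=head, relation=rel, tail=tail))
    return AnnotatedSentence(text=text, triples=triples)
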