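"""Word-vector table and per-character candidate-word matching.

The character encoder is augmented with lexicon words: for each character
position the table is scanned for every word that occurs in the sentence
as a contiguous substring covering that position. The matched words (their
vectors) are later injected into the character stream by the fusion
attention. Matching is sentence-occurrence based — a word must actually
occur in the sentence, not merely contain the character — which keeps the
candidates context-relevant, mirroring lattice-style lexicon augmentation.

Each position carries exactly ``m`` candidate slots; unfilled slots hold a
designated PAD entry whose vector is all zeros.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PAD_WORD = "PAD"

#: default cap on matched-word length (characters); bounds the scan window
DEFAULT_MAX_WORD_LEN = 8


class WordVectorLoadError(ValueError):
    """Raised for malformed word-vector files; names the offending line."""


@dataclass
class WordVectorTable:
    """word → fixed-dimension vector lookup.

    ``entries`` maps unique non-empty word strings to 1-D float vectors of
    length ``word_dim``. Absent words are reported via ``None`` from
    :meth:`get`, never via a zero vector, so a stored zero vector remains
    distinguishable from a miss.
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    word_dim: int = 0

    def __post_init__(self) -> None:
        for w, v in self.entries.items():
            if not w:
                raise ValueError("empty word in table")
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.word_dim,):
                raise ValueError(
                    f"vector for {w!r} has shape {v.shape}, expected ({self.word_dim},)")
            self.entries[w] = v

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def get(self, word: str) -> np.ndarray | None:
        return self.entries.get(word)

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self.entries[word]
        except KeyError:
            raise KeyError(f"word not in table: {word!r}") from None

    @property
    def pad_vector(self) -> np.ndarray:
        return np.zeros(self.word_dim)

    def max_word_length(self) -> int:
        return max((len(w) for w in self.entries), default=0)

    def save(self, path: str | Path) -> None:
        """Write in word2vec text format: header "count dim", then rows."""
        with io.open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.entries)} {self.word_dim}\n")
            for word, vec in self.entries.items():
                comps = " ".join(repr(float(x)) for x in vec)
                fh.write(f"{word} {comps}\n")


def load_word_vectors(path: str | Path,
                      expected_dim: int | None = None) -> WordVectorTable:
    """Load a word2vec-text-format table.

    The first line is ``"<count> <dim>"``; each following line is a word and
    ``dim`` space-separated floats. Words containing spaces are not
    supported by the dialect. Errors (malformed header, ragged rows,
    duplicate words, count mismatch) raise :class:`WordVectorLoadError`
    naming the 1-based offending line.
    """
    path = Path(path)
    with io.open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise WordVectorLoadError(f"{path}: line 1: empty or missing header")
        parts = header.split()
        if len(parts) != 2:
            raise WordVectorLoadError(
                f"{path}: line 1: header must be '<count> <dim>', got {header.strip()!r}")
        try:
            count, dim = int(parts[0]), int(parts[1])
        except ValueError:
            raise WordVectorLoadError(
                f"{path}: line 1: non-integer header fields {header.strip()!r}") from None
        if count < 0 or dim <= 0:
            raise WordVectorLoadError(f"{path}: line 1: invalid header values")
        if expected_dim is not None and dim != expected_dim:
            raise WordVectorLoadError(
                f"{path}: dimension {dim} does not match expected {expected_dim}")
        entries: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = line.rstrip("\n").split(" ")
            word = row[0]
            if not word:
                raise WordVectorLoadError(f"{path}: line {lineno}: empty word")
            if word in entries:
                raise WordVectorLoadError(
                    f"{path}: line {lineno}: duplicate word {word!r}")
            if len(row) - 1 != dim:
                raise WordVectorLoadError(
                    f"{path}: line {lineno}: expected {dim} components, got {len(row) - 1}")
            try:
                vec = np.array([float(x) for x in row[1:]], dtype=np.float64)
            except ValueError:
                raise WordVectorLoadError(
                    f"{path}: line {lineno}: non-numeric vector component") from None
            entries[word] = vec
        if len(entries) != count:
            raise WordVectorLoadError(
                f"{path}: header declares {count} words but file has {len(entries)}")
    return WordVectorTable(entries=entries, word_dim=dim)


@dataclass(frozen=True)
class MatchEntry:
    """One candidate slot at a character position."""

    word: str
    vector: np.ndarray
    is_pad: bool


@dataclass
class CharWordMatches:
    """Per-position candidate words, padded to exactly ``m`` slots each."""

    per_position: list[list[MatchEntry]]
    m: int

    def __post_init__(self) -> None:
        for i, slots in enumerate(self.per_position):
            if len(slots) != self.m:
                raise ValueError(
                    f"position {i} has {len(slots)} slots, expected m={self.m}")

    def __len__(self) -> int:
        return len(self.per_position)

    def words_at(self, i: int) -> list[str]:
        """Non-PAD candidate words at position ``i``."""
        return [e.word for e in self.per_position[i] if not e.is_pad]

    def vectors(self) -> np.ndarray:
        """(n, m, word_dim) candidate-vector array (PAD slots are zero)."""
        return np.stack([
            np.stack([e.vector for e in slots]) for slots in self.per_position
        ])

    def pad_mask(self) -> np.ndarray:
        """(n, m) boolean array, True where the slot is PAD."""
        return np.array([[e.is_pad for e in slots] for slots in self.per_position])

    def truncated(self, n: int) -> "CharWordMatches":
        return CharWordMatches(per_position=self.per_position[:n], m=self.m)


def find_occurring_words(sentence: str, table: WordVectorTable,
                         max_word_len: int = DEFAULT_MAX_WORD_LEN
                         ) -> list[tuple[int, str]]:
    """All (start, word) pairs where a table word occurs in the sentence.

    Scans every window of length 1..max_word_len; character (not byte)
    offsets.
    """
    n = len(sentence)
    hits: list[tuple[int, str]] = []
    limit = min(max_word_len, table.max_word_length(), n)
    for start in range(n):
        for length in range(1, min(limit, n - start) + 1):
            cand = sentence[start:start + length]
            if cand in table:
                hits.append((start, cand))
    return hits


def match_candidate_words(sentence: str, table: WordVectorTable, m: int,
                          max_word_len: int = DEFAULT_MAX_WORD_LEN
                          ) -> CharWordMatches:
    """Per-character candidate words, padded/truncated to exactly ``m``.

    A word is a candidate at position ``i`` when some occurrence of it in
    the sentence covers ``i``. When more than ``m`` distinct words match,
    the ``m`` longest are kept (ties: earlier first occurrence, then
    lexicographic). Fewer than ``m`` matches are padded with PAD slots
    carrying the zero vector.
    """
    if m <= 0:
        raise ValueError(f"m must be >= 1, got {m}")
    if not sentence:
        raise ValueError("sentence must be non-empty")
    n = len(sentence)
    # word -> first occurrence start, per covered position
    covering: list[dict[str, int]] = [dict() for _ in range(n)]
    for start, word in find_occurring_words(sentence, table, max_word_len):
        for i in range(start, start + len(word)):
            if word not in covering[i] or start < covering[i][word]:
                covering[i][word] = start
    pad = MatchEntry(PAD_WORD, table.pad_vector, True)
    per_position: list[list[MatchEntry]] = []
    for i in range(n):
        ranked = sorted(covering[i].items(),
                        key=lambda kv: (-len(kv[0]), kv[1], kv[0]))
        slots = [MatchEntry(w, table[w], False) for w, _ in ranked[:m]]
        slots.extend([pad] * (m - len(slots)))
        per_position.append(slots)
    return CharWordMatches(per_position=per_position, m=m)


def random_table(words: list[str], word_dim: int,
                 rng: np.random.Generator) -> WordVectorTable:
    """Unit-normalised random-vector table over the given words."""
    entries: dict[str, np.ndarray] = {}
    for w in words:
        v = rng.normal(size=word_dim)
        entries[w] = v / np.linalg.norm(v)
    return WordVectorTable(entries=entries, word_dim=word_dim)
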