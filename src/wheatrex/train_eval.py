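"""Training and exact-match evaluation of the cascade extractor.

Training supervises the pointer taggers with binary cross-entropy under
gold-subject teacher forcing: head start/end pointers are supervised on
all gold head spans of a sentence, and for each step one gold head is
sampled uniformly and its relation-specific tail pointers are supervised
(all other relations' labels are zero, providing the negative signal).
The objective is the head tagger's mean BCE plus the tail taggers' mean
BCE — equal weight per tagger stage, so the sparse head labels are not
drowned by the much larger tail label tensor. Within the tail stage,
positive cells are up-weighted by the schema size: a tail tensor holds
only a handful of 1s among 2·n·R cells, and an unweighted mean would let
the negatives pin every probability to zero. Gradients are clipped to
global norm 1.0 and applied with Adam.

Evaluation is exact-match: a predicted triple is correct iff its head
span, relation label, and tail span all equal a gold triple. With
N_pred / N_pred^right / N_gold the number of predicted / correctly
predicted / gold triples,

    P = N_pred^right / N_pred,  R = N_pred^right / N_gold,
    F1 = 2 P R / (P + R),

with P := 0 when nothing is predicted and F1 := 0 when P + R = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus_io import AnnotatedSentence, PointerLabels, spans_to_labels
from .encoder import DCWFEncoder
from .extractor import PointerParams, Span, Triple, extract_triples
from .lexicon import CharWordMatches, WordVectorTable, match_candidate_words
from .nn import Tensor
from .nn import autograd as ag
from .nn.optim import OPTIMIZERS, clip_grad_norm


@dataclass
class MetricCounts:
    n_pred: int
    n_right: int
    n_gold: int

    def __post_init__(self) -> None:
        if min(self.n_pred, self.n_right, self.n_gold) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_right > min(self.n_pred, self.n_gold):
            raise ValueError("n_right cannot exceed n_pred or n_gold")

    def __add__(self, other: "MetricCounts") -> "MetricCounts":
        return MetricCounts(self.n_pred + other.n_pred,
                            self.n_right + other.n_right,
                            self.n_gold + other.n_gold)


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    counts: MetricCounts

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TrainConfig:
    learning_rate: float = 3e-3
    batch_size: int = 4
    epochs: int = 50
    threshold: float = 0.5
    seed: int = 0
    optimizer: str = "adam"
    grad_clip: float = 1.0
    eval_every: int = 0          #: evaluate train F1 every k epochs (0 = never)
    early_stop_f1: float | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def full_scale_preset(cls, **overrides) -> "TrainConfig":
        """Full-scale fine-tuning settings: Adam, lr 1e-5, batch size 4."""
        base = dict(learning_rate=1e-5, batch_size=4, optimizer="adam")
        base.update(overrides)
        return cls(**base)


class ExtractionModel:
    """Encoder + pointer network + lexicon: the trainable unit."""

    def __init__(self, encoder: DCWFEncoder, pointer: PointerParams,
                 table: WordVectorTable):
        if encoder.config.word_dim != table.word_dim:
            raise ValueError(
                f"encoder word_dim {encoder.config.word_dim} != table dim "
                f"{table.word_dim}")
        self.encoder = encoder
        self.pointer = pointer
        self.table = table

    @property
    def schema(self) -> list[str]:
        return self.pointer.schema

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.pointer.parameters()

    def matches(self, sentence: str) -> CharWordMatches:
        cfg = self.encoder.config
        return match_candidate_words(sentence, self.table, cfg.m,
                                     cfg.max_word_len)

    def predict(self, sentence: str, threshold: float = 0.5) -> set[Triple]:
        if not sentence:
            return set()
        truncated = sentence[:self.encoder.config.max_len]
        _, m2 = self.encoder.encode(truncated, self.matches(truncated))
        return extract_triples(truncated, m2, self.pointer, threshold)


def pointer_loss(probs: np.ndarray, labels: np.ndarray,
                 eps: float = 1e-7) -> float:
    """Mean binary cross-entropy between probabilities and 0/1 labels.

    Probabilities are clipped to [eps, 1 - eps] before the logarithm.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    p = np.clip(probs, eps, 1.0 - eps)
    return float(np.mean(-(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))))


def _sentence_loss(model: ExtractionModel, sentence: AnnotatedSentence,
                   matches: CharWordMatches, labels: PointerLabels,
                   rng: np.random.Generator) -> Tensor:
    """Taped BCE for one sentence (head pointers + one sampled subject)."""
    text = sentence.text[:model.encoder.config.max_len]
    n = len(text)
    _, m2 = model.encoder.forward(text, matches)
    head_logits = model.pointer.head_logits(m2)                  # (n, 2)
    head_gold = np.stack([labels.head_start[:n], labels.head_end[:n]], axis=1)
    loss = ag.bce_with_logits(head_logits, head_gold).mean()

    head_keys = [k for k in labels.tails if k[1] <= n]
    if head_keys:
        hs, he = head_keys[rng.integers(len(head_keys))]
        v_sub = m2[hs:he].mean(axis=0)
        tail_start, tail_end = model.pointer.tail_logits(m2, v_sub)  # (n, R)
        ts_gold, te_gold = labels.tails[(hs, he)]
        r = len(model.schema)
        tail_loss = (
            ag.bce_with_logits(tail_start, ts_gold[:, :n].T, pos_weight=r).sum()
            + ag.bce_with_logits(tail_end, te_gold[:, :n].T, pos_weight=r).sum())
        loss = loss + tail_loss * (1.0 / (2 * n * r))
    return loss


def train(corpus: list[AnnotatedSentence], model: ExtractionModel,
          config: TrainConfig,
          dev: list[AnnotatedSentence] | None = None) -> list[dict]:
    """Optimise the model in place; returns the per-epoch metric log.

    Each log entry carries ``epoch`` and mean ``loss``; when
    ``config.eval_every`` > 0, every k-th entry also carries exact-match
    ``f1`` on ``dev`` (or on the training corpus when no dev split is
    given), and training stops early once it reaches
    ``config.early_stop_f1``.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    if sum(len(s.triples) for s in corpus) == 0:
        raise ValueError("training corpus contains no gold triples")
    schema = model.schema
    prepared = []
    for sent in corpus:
        sent.validate(schema)
        text = sent.text[:model.encoder.config.max_len]
        prepared.append((sent, model.matches(text),
                         spans_to_labels(sent, schema)))
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    optimizer = OPTIMIZERS[config.optimizer](params, lr=config.learning_rate)
    history: list[dict] = []
    eval_on = dev if dev else corpus
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(prepared))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            group = order[lo:lo + config.batch_size]
            optimizer.zero_grad()
            for idx in group:
                sent, matches, labels = prepared[idx]
                loss = _sentence_loss(model, sent, matches, labels, rng)
                loss = loss * (1.0 / len(group))
                loss.backward()
                losses.append(float(loss.data) * len(group))
            clip_grad_norm(params, config.grad_clip)
            optimizer.step()
        entry = {"epoch": epoch, "loss": float(np.mean(losses))}
        if config.eval_every and epoch % config.eval_every == 0:
            result = evaluate_model(model, eval_on, config.threshold)
            entry["f1"] = result.f1
            history.append(entry)
            if (config.early_stop_f1 is not None
                    and result.f1 >= config.early_stop_f1):
                break
        else:
            history.append(entry)
    return history


# ---------------------------------------------------------------------------
# evaluation


def _key(triple: Triple, text_only: bool):
    if text_only:
        return (triple.head.text, triple.relation, triple.tail.text)
    return (triple.head.start, triple.head.end, triple.relation,
            triple.tail.start, triple.tail.end)


def evaluate(predicted: list[set[Triple]], gold: list[set[Triple]],
             text_only: bool = False) -> EvalResult:
    """Micro-averaged exact-match precision / recall / F1 over sentences."""
    if len(predicted) != len(gold):
        raise ValueError("predicted and gold collections are not aligned")
    counts = MetricCounts(0, 0, 0)
    for pred, gld in zip(predicted, gold):
        pk = {_key(t, text_only) for t in pred}
        gk = {_key(t, text_only) for t in gld}
        counts = counts + MetricCounts(len(pk), len(pk & gk), len(gk))
    return _result_from_counts(counts)


def _result_from_counts(counts: MetricCounts) -> EvalResult:
    p = counts.n_right / counts.n_pred if counts.n_pred else 0.0
    r = counts.n_right / counts.n_gold if counts.n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return EvalResult(precision=p, recall=r, f1=f1, counts=counts)


def evaluate_model(model: ExtractionModel, corpus: list[AnnotatedSentence],
                   threshold: float = 0.5, text_only: bool = False) -> EvalResult:
    predicted = [model.predict(s.text, threshold) for s in corpus]
    gold = [{t for t in s.triples
             if t.head.end <= model.encoder.config.max_len
             and t.tail.end <= model.encoder.config.max_len}
            for s in corpus]
    return evaluate(predicted, gold, text_only)
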