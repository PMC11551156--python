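"""Desk-scale benchmark procedures.

These routines exercise the full stack end to end at sizes a laptop CPU
handles in minutes, and are what the repository's acceptance script runs:

* :func:`overlap_demo` — the canonical annotation walk-through: one
  variety head carrying two unit-bearing attribute tails is pushed through
  the "01" label scheme and proximity decoding, and must come back as two
  triples sharing the head span.
* :func:`proximity_demo` — the head-extraction walk-through: the printed
  start/end marker rows decode to three candidate entities, with the start
  inside "827g/L" pairing to the "L" end rather than a nearer digit.
* :func:`overfit_check` — memorisation: a tiny model (2 encoder layers,
  width 64, fusion after layer 1, m = 3) trained on 50 generated sentences
  must reach exact-match F1 >= 0.9 on those sentences within 200 epochs
  (median over 3 training seeds).
* :func:`ablation_check` — direction of the architecture ablations on a
  500-sentence generated benchmark: the full model's held-out F1 should
  not fall below the no-fusion and no-BiLSTM variants' (median over 3
  seeds), the expected ordering for this architecture family, checked at desk scale.
"""

from __future__ import annotations

import numpy as np

from .corpus_io import labels_to_spans, spans_to_labels
from .extractor import Span, Triple, decode_spans_proximity
from .corpus_io import AnnotatedSentence
from .model import CascadeTripleExtractor
from .synthgen import SynthConfig, generate_corpus

OVERLAP_TEXT = "Zhongmai 159, 827 g/L unit weight, crude protein content 14.8%."
OVERLAP_SCHEMA = ["Unit weight", "Crude protein content"]


def overlap_sentence() -> AnnotatedSentence:
    """The canonical single-entity-overlap example sentence."""
    head = Span.from_offsets(OVERLAP_TEXT, 0, 12)     # "Zhongmai 159"
    return AnnotatedSentence(text=OVERLAP_TEXT, triples=[
        Triple(head, "Unit weight", Span.from_offsets(OVERLAP_TEXT, 14, 21)),
        Triple(head, "Crude protein content",
               Span.from_offsets(OVERLAP_TEXT, 57, 62)),
    ])


def overlap_demo() -> dict:
    """Annotation → "01" labels → decoded triples, on the overlap example."""
    sent = overlap_sentence()
    labels = spans_to_labels(sent, OVERLAP_SCHEMA)
    decoded = labels_to_spans(labels, sent.text)
    heads = {t.head.text for t in decoded.triples}
    return {
        "n_triples": len(decoded.triples),
        "shared_heads": sorted(heads),
        "triples": sorted((t.head.text, t.relation, t.tail.text)
                          for t in decoded.triples),
    }


PROXIMITY_TEXT = "Zhongmai 159,827g/L,14.8%"
#: printed marker rows: starts at 'Z', '8', '1'; ends at '9', 'L', '%'
PROXIMITY_STARTS = (0, 13, 20)
PROXIMITY_ENDS = (11, 18, 24)


def proximity_demo() -> dict:
    """Nearest-end pairing of the printed start/end label rows."""
    starts = np.zeros(len(PROXIMITY_TEXT), dtype=int)
    ends = np.zeros(len(PROXIMITY_TEXT), dtype=int)
    starts[list(PROXIMITY_STARTS)] = 1
    ends[list(PROXIMITY_ENDS)] = 1
    spans = decode_spans_proximity(starts, ends, PROXIMITY_TEXT)
    return {
        "n_heads": len(spans),
        "texts": [s.text for s in spans],
    }


def overfit_check(seed: int = 1, n_sentences: int = 50, max_epochs: int = 200,
                  n_seeds: int = 3, target_f1: float = 0.9) -> dict:
    """Train-set memorisation of the tiny configuration.

    One fixed 50-sentence corpus; ``n_seeds`` independent weight/shuffle
    seeds; early stopping once the train F1 comfortably exceeds the
    target. Returns per-seed F1 (at the stopping epoch) and the median.
    """
    corpus = generate_corpus(SynthConfig(
        n_sentences=n_sentences, seed=seed % (2 ** 31), splits=(1.0, 0.0, 0.0)))
    per_seed = []
    for k in range(n_seeds):
        est = CascadeTripleExtractor(
            layers=2, fusion_layer=1, hidden_dim=64, m=3,
            lexicon=corpus.table, schema=corpus.schema,
            epochs=max_epochs, eval_every=10,
            early_stop_f1=max(target_f1 + 0.02, 0.92),
            seed=(seed * 97 + k) % (2 ** 31))
        est.fit(corpus.train)
        per_seed.append({"f1": est.score(corpus.train),
                         "epochs": est.history_[-1]["epoch"]})
    return {
        "per_seed": per_seed,
        "median_f1": float(np.median([r["f1"] for r in per_seed])),
        "n_sentences": n_sentences,
    }


ABLATION_VARIANTS = {
    "full": {},
    "no_fusion": {"use_fusion": False},
    "no_bilstm": {"use_bilstm": False},
}


def ablation_check(seed: int = 1, n_sentences: int = 500,
                   epochs: int = 6, n_seeds: int = 3) -> dict:
    """Held-out F1 of the full model vs its two single ablations.

    All variants share corpora and seeds; training is deliberately short
    (6 epochs) so differences in learning speed — where the lexicon cues
    and the recurrent layer earn their keep — are visible.
    """
    corpus = generate_corpus(SynthConfig(
        n_sentences=n_sentences, seed=(seed * 131) % (2 ** 31)))
    results: dict[str, dict] = {}
    for name, overrides in ABLATION_VARIANTS.items():
        scores = []
        for k in range(n_seeds):
            est = CascadeTripleExtractor(
                layers=2, fusion_layer=1, hidden_dim=64, m=3,
                lexicon=corpus.table, schema=corpus.schema, epochs=epochs,
                seed=(seed * 389 + k) % (2 ** 31), **overrides)
            est.fit(corpus.train)
            scores.append(est.score(corpus.test))
        results[name] = {"per_seed": scores,
                         "median_f1": float(np.median(scores))}
    results["n_sentences"] = n_sentences
    return results
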