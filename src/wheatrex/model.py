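"""Scikit-learn-style estimator wrapping the full extraction pipeline.

:class:`CascadeTripleExtractor` composes the lexicon matcher, the fusion
encoder and the cascading pointer network behind ``fit`` / ``predict`` /
``score``, so it plugs into sklearn model selection (``get_params`` /
``set_params`` / ``clone``). ``fit`` takes annotated sentences; ``predict``
takes raw texts and returns extracted triples per text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .corpus_io import AnnotatedSentence
from .encoder import CharVocab, DCWFEncoder, EncoderConfig
from .extractor import PointerParams, Triple
from .lexicon import WordVectorTable
from .train_eval import (EvalResult, ExtractionModel, TrainConfig, evaluate,
                         train)


def _as_sentences(X) -> list[AnnotatedSentence]:
    out = []
    for item in X:
        if isinstance(item, AnnotatedSentence):
            out.append(item)
        elif isinstance(item, dict):
            out.append(AnnotatedSentence.from_dict(item))
        else:
            raise TypeError(
                f"expected AnnotatedSentence or dict, got {type(item).__name__}")
    return out


class CascadeTripleExtractor(BaseEstimator):
    """Joint entity–relation triple extractor.

    Parameters mirror the two config objects: architecture (``layers`` …
    ``mask_pad``) and optimisation (``learning_rate`` … ``epochs``). The
    relation ``schema`` and the word-vector ``lexicon`` may be given
    up front; when omitted, the schema is collected from the training
    annotations and the lexicon defaults to an empty table (candidate
    matching then yields only PAD slots, i.e. plain character encoding).

    Attributes set by :meth:`fit` (trailing underscore): ``model_``,
    ``schema_``, ``vocab_``, ``history_``.
    """

    def __init__(self, layers: int = 2, fusion_layer: int = 1,
                 hidden_dim: int = 64, word_dim: int = 200, m: int = 3,
                 heads: int = 4, max_len: int = 200,
                 use_fusion: bool = True, use_bilstm: bool = True,
                 mask_pad: bool = False, max_word_len: int = 8,
                 schema: list[str] | None = None,
                 lexicon: WordVectorTable | None = None,
                 learning_rate: float = 3e-3, batch_size: int = 4,
                 epochs: int = 50, threshold: float = 0.5,
                 optimizer: str = "adam", grad_clip: float = 1.0,
                 eval_every: int = 0, early_stop_f1: float | None = None,
                 seed: int = 0):
        self.layers = layers
        self.fusion_layer = fusion_layer
        self.hidden_dim = hidden_dim
        self.word_dim = word_dim
        self.m = m
        self.heads = heads
        self.max_len = max_len
        self.use_fusion = use_fusion
        self.use_bilstm = use_bilstm
        self.mask_pad = mask_pad
        self.max_word_len = max_word_len
        self.schema = schema
        self.lexicon = lexicon
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.threshold = threshold
        self.optimizer = optimizer
        self.grad_clip = grad_clip
        self.eval_every = eval_every
        self.early_stop_f1 = early_stop_f1
        self.seed = seed

    # -- config assembly ---------------------------------------------------
    def _encoder_config(self, word_dim: int) -> EncoderConfig:
        return EncoderConfig(
            layers=self.layers, fusion_layer=self.fusion_layer,
            hidden_dim=self.hidden_dim, word_dim=word_dim, m=self.m,
            heads=self.heads, max_len=self.max_len, use_fusion=self.use_fusion,
            use_bilstm=self.use_bilstm, mask_pad=self.mask_pad,
            max_word_len=self.max_word_len, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, threshold=self.threshold, seed=self.seed,
            optimizer=self.optimizer, grad_clip=self.grad_clip,
            eval_every=self.eval_every, early_stop_f1=self.early_stop_f1)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None, dev=None) -> "CascadeTripleExtractor":
        """Train on annotated sentences (gold triples ride along in X)."""
        sentences = _as_sentences(X)
        if not sentences:
            raise ValueError("training set is empty")
        schema = self.schema
        if schema is None:
            schema = sorted({t.relation for s in sentences for t in s.triples})
        if not schema:
            raise ValueError("no relations: supply a schema or annotated triples")
        table = self.lexicon
        if table is None:
            table = WordVectorTable(entries={}, word_dim=self.word_dim)
        vocab = CharVocab.build([s.text for s in sentences])
        encoder = DCWFEncoder(self._encoder_config(table.word_dim), vocab)
        pointer = PointerParams(self.hidden_dim, schema,
                                np.random.default_rng(self.seed + 1))
        model = ExtractionModel(encoder, pointer, table)
        dev_sentences = _as_sentences(dev) if dev else None
        self.history_ = train(sentences, model, self._train_config(),
                              dev=dev_sentences)
        self.model_ = model
        self.schema_ = list(schema)
        self.vocab_ = vocab
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict(self, X) -> list[list[Triple]]:
        """Extract triples from raw texts (sorted for reproducibility)."""
        self._check_fitted()
        texts = [x.text if isinstance(x, AnnotatedSentence) else str(x)
                 for x in X]
        return [sorted(self.model_.predict(t, self.threshold)) for t in texts]

    def evaluate(self, X) -> EvalResult:
        """Exact-match P/R/F1 against the gold triples carried in X."""
        self._check_fitted()
        sentences = _as_sentences(X)
        predicted = [set(p) for p in self.predict(sentences)]
        gold = [{t for t in s.triples if t.head.end <= self.max_len
                 and t.tail.end <= self.max_len} for s in sentences]
        return evaluate(predicted, gold)

    def score(self, X, y=None) -> float:
        """Exact-match F1 (the estimator's native score)."""
        return self.evaluate(X).f1

    # -- persistence -------------------------------------------------------
    def save(self, model_dir: str | Path) -> None:
        self._check_fitted()
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "params": {k: v for k, v in self.get_params().items()
                       if k != "lexicon"},
            "schema": self.schema_,
            "vocab": self.vocab_.to_dict(),
            "encoder_config": self.model_.encoder.config.to_dict(),
        }
        with open(model_dir / "config.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, ensure_ascii=False)
        arrays = (self.model_.encoder.state_arrays()
                  + self.model_.pointer.state_arrays())
        np.savez(model_dir / "weights.npz",
                 **{f"p{i}": a for i, a in enumerate(arrays)})
        self.model_.table.save(model_dir / "vectors.txt")

    @classmethod
    def load(cls, model_dir: str | Path) -> "CascadeTripleExtractor":
        from .lexicon import load_word_vectors

        model_dir = Path(model_dir)
        with open(model_dir / "config.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        table = load_word_vectors(model_dir / "vectors.txt")
        params = meta["params"]
        params["schema"] = meta["schema"]
        est = cls(**params)
        est.lexicon = table
        vocab = CharVocab.from_dict(meta["vocab"])
        encoder = DCWFEncoder(EncoderConfig.from_dict(meta["encoder_config"]),
                              vocab)
        pointer = PointerParams(est.hidden_dim, meta["schema"],
                                np.random.default_rng(est.seed + 1))
        model = ExtractionModel(encoder, pointer, table)
        with np.load(model_dir / "weights.npz") as npz:
            arrays = [npz[f"p{i}"] for i in range(len(npz.files))]
        n_enc = len(encoder.parameters())
        encoder.load_state_arrays(arrays[:n_enc])
        pointer.load_state_arrays(arrays[n_enc:])
        est.model_ = model
        est.schema_ = meta["schema"]
        est.vocab_ = vocab
        est.history_ = []
        return est
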