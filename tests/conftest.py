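import numpy as np
import pytest

from wheatrex.corpus_io import AnnotatedSentence
from wheatrex.extractor import Span, Triple
from wheatrex.lexicon import WordVectorTable


@pytest.fixture
def tiny_table() -> WordVectorTable:
    """Small deterministic word-vector table for matching tests."""
    rng = np.random.default_rng(42)
    words = ["ab", "bc", "abc", "wheat", "grain", "g/L", "%", "cm"]
    return WordVectorTable(
        entries={w: rng.normal(size=4) for w in words}, word_dim=4)


def make_fig2_sentence() -> AnnotatedSentence:
    """The canonical overlap example: one variety head, two attribute tails.

    "Zhongmai 159, 827 g/L unit weight, crude protein content 14.8%."
    """
    text = "Zhongmai 159, 827 g/L unit weight, crude protein content 14.8%."
    head = Span.from_offsets(text, 0, 12)            # "Zhongmai 159"
    tail1 = Span.from_offsets(text, 14, 21)          # "827 g/L"
    tail2 = Span.from_offsets(text, 57, 62)          # "14.8%"
    assert head.text == "Zhongmai 159"
    assert tail1.text == "827 g/L"
    assert tail2.text == "14.8%"
    return AnnotatedSentence(text=text, triples=[
        Triple(head=head, relation="Unit weight", tail=tail1),
        Triple(head=head, relation="Crude protein content", tail=tail2),
    ])


@pytest.fixture
def fig2_sentence() -> AnnotatedSentence:
    return make_fig2_sentence()
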