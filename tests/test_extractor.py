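"""Pointer scoring, proximity span decoding, and cascade assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatrex.extractor import (PointerParams, Span, Triple, binarize,
                                decode_spans_proximity, extract_triples,
                                head_pointer_probs, subject_rep,
                                tail_pointer_probs)

SCHEMA = ["Unit weight", "Crude protein content", "Plant height"]


@pytest.fixture
def params():
    return PointerParams(d_h=8, schema=SCHEMA, rng=np.random.default_rng(5))


def brute_force_proximity(starts, ends):
    """Oracle: for each start s, minimise e - s over all ends e >= s."""
    spans = []
    end_idx = [i for i, v in enumerate(ends) if v]
    for s, v in enumerate(starts):
        if not v:
            continue
        candidates = [e for e in end_idx if e >= s]
        if candidates:
            e = min(candidates, key=lambda e: e - s)
            spans.append((s, e + 1))
    return spans


class TestSpan:
    def test_text_must_match_slice(self):
        s = Span.from_offsets("wheat grain", 0, 5)
        assert s.text == "wheat"
        with pytest.raises(ValueError):
            Span(0, 5, "grain").validate_against("wheat grain")

    @pytest.mark.parametrize("start,end", [(-1, 2), (3, 3), (5, 2)])
    def test_degenerate_offsets_rejected(self, start, end):
        with pytest.raises(ValueError):
            Span(start, end)


class TestHeadPointerProbs:
    def test_outputs_are_probabilities(self, params):
        m2 = np.random.default_rng(0).normal(size=(7, 8))
        ps, pe = head_pointer_probs(m2, params)
        assert ps.shape == pe.shape == (7,)
        assert np.all((ps > 0) & (ps < 1)) and np.all((pe > 0) & (pe < 1))

    def test_zero_weights_give_half(self):
        params = PointerParams(d_h=4, schema=["r"], rng=np.random.default_rng(0))
        params.head_w.data[:] = 0.0
        params.head_b.data[:] = 0.0
        ps, pe = head_pointer_probs(np.ones((3, 4)), params)
        np.testing.assert_allclose(ps, 0.5)
        np.testing.assert_allclose(pe, 0.5)

    def test_matches_scalar_oracle(self):
        """sigmoid(w . M2_i + b) reproduced by direct substitution."""
        params = PointerParams(d_h=2, schema=["r"], rng=np.random.default_rng(0))
        params.head_w.data = np.array([[1.0, -1.0], [2.0, 0.5]])
        params.head_b.data = np.array([0.1, -0.2])
        m2 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ps, pe = head_pointer_probs(m2, params)
        for i in range(3):
            zs = m2[i] @ params.head_w.data[:, 0] + 0.1
            ze = m2[i] @ params.head_w.data[:, 1] - 0.2
            assert ps[i] == pytest.approx(1 / (1 + np.exp(-zs)))
            assert pe[i] == pytest.approx(1 / (1 + np.exp(-ze)))

    def test_nonfinite_states_rejected(self, params):
        m2 = np.full((3, 8), np.nan)
        with pytest.raises(ValueError):
            head_pointer_probs(m2, params)


class TestBinarize:
    @pytest.mark.parametrize("prob,thr,label", [
        (0.7, 0.5, 1), (0.5, 0.5, 0), (0.5, 0.4, 1), (0.3, 0.5, 0)])
    def test_strict_threshold(self, prob, thr, label):
        assert binarize(np.array([prob]), thr)[0] == label

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_out_of_range(self, thr):
        with pytest.raises(ValueError):
            binarize(np.array([0.5]), thr)


class TestProximityDecoding:
    def test_three_entity_worked_example(self):
        """The printed start/end label rows: starts at 'Z', '8' and '1';
        ends at '9' (of 159), 'L' and '%'. The start at '8' must pair with
        the following 'L', giving the unit-bearing span "827g/L"."""
        text = "Zhongmai 159,827g/L,14.8%"
        starts = np.zeros(len(text), dtype=int)
        ends = np.zeros(len(text), dtype=int)
        starts[[0, 13, 20]] = 1       # 'Z', '8', '1'
        ends[[11, 18, 24]] = 1        # '9', 'L', '%'
        spans = decode_spans_proximity(starts, ends, text)
        assert [s.text for s in spans] == ["Zhongmai 159", "827g/L", "14.8%"]
        assert len(spans) == 3

    def test_all_zero_labels_decode_to_nothing(self):
        assert decode_spans_proximity(np.zeros(9), np.zeros(9)) == []

    def test_start_without_end_dropped_and_end_reusable(self):
        #        0  1  2  3  4
        starts = [1, 1, 0, 0, 1]
        ends = [0, 0, 1, 0, 0]
        spans = decode_spans_proximity(np.array(starts), np.array(ends))
        assert [(s.start, s.end) for s in spans] == [(0, 3), (1, 3)]

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 2 ** 20 - 1), st.integers(0, 2 ** 20 - 1),
           st.integers(1, 20))
    def test_matches_exhaustive_oracle(self, s_bits, e_bits, n):
        starts = np.array([(s_bits >> i) & 1 for i in range(n)])
        ends = np.array([(e_bits >> i) & 1 for i in range(n)])
        got = [(s.start, s.end) for s in decode_spans_proximity(starts, ends)]
        assert got == brute_force_proximity(starts, ends)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_spans_proximity(np.zeros(3), np.zeros(4))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15),
           st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15))
    def test_threshold_monotonicity(self, ps, pe):
        """Raising the threshold never increases the decoded span count."""
        n = min(len(ps), len(pe))
        ps, pe = np.array(ps[:n]), np.array(pe[:n])
        counts = [len(decode_spans_proximity(binarize(ps, t), binarize(pe, t)))
                  for t in (0.3, 0.5, 0.7)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_decoder_idempotence(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 20))
            starts = rng.integers(0, 2, n)
            ends = rng.integers(0, 2, n)
            spans = decode_spans_proximity(starts, ends)
            s2 = np.zeros(n, dtype=int)
            e2 = np.zeros(n, dtype=int)
            for sp in spans:
                s2[sp.start] = 1
                e2[sp.end - 1] = 1
            again = decode_spans_proximity(s2, e2)
            assert set((sp.start, sp.end) for sp in spans) \
                == set((sp.start, sp.end) for sp in again)


class TestSubjectRep:
    def test_single_position_is_that_vector(self):
        m2 = np.arange(12.0).reshape(4, 3)
        np.testing.assert_array_equal(subject_rep(m2, Span(2, 3)), m2[2])

    def test_constant_sequence_gives_the_constant(self):
        m2 = np.full((5, 3), 2.5)
        np.testing.assert_array_equal(subject_rep(m2, Span(1, 4)), [2.5] * 3)

    def test_mean_matches_oracle(self):
        rng = np.random.default_rng(3)
        m2 = rng.normal(size=(6, 4))
        np.testing.assert_allclose(subject_rep(m2, Span(1, 4)),
                                   (m2[1] + m2[2] + m2[3]) / 3)

    def test_span_beyond_sequence_rejected(self):
        with pytest.raises(ValueError):
            subject_rep(np.zeros((3, 2)), Span(1, 5))


class TestTailPointerProbs:
    def test_shape_contract(self, params):
        m2 = np.random.default_rng(1).normal(size=(6, 8))
        out = tail_pointer_probs(m2, np.zeros(8), params)
        assert set(out) == set(SCHEMA)
        for ts, te in out.values():
            assert ts.shape == te.shape == (6,)

    def test_zero_subject_reduces_to_unconditioned_scoring(self, params):
        """v_sub = 0 leaves only the relation's own affine map of M2."""
        m2 = np.random.default_rng(2).normal(size=(5, 8))
        out = tail_pointer_probs(m2, np.zeros(8), params)
        for j, rel in enumerate(SCHEMA):
            zs = m2 @ params.tail_w_start.data[:, j] + params.tail_b_start.data[j]
            np.testing.assert_allclose(out[rel][0], 1 / (1 + np.exp(-zs)))

    def test_per_relation_independence(self, params):
        m2 = np.random.default_rng(3).normal(size=(5, 8))
        v = np.random.default_rng(4).normal(size=8)
        before = tail_pointer_probs(m2, v, params)
        params.tail_w_start.data[:, 0] += 10.0   # perturb one relation only
        after = tail_pointer_probs(m2, v, params)
        assert not np.allclose(before[SCHEMA[0]][0], after[SCHEMA[0]][0])
        for rel in SCHEMA[1:]:
            np.testing.assert_array_equal(before[rel][0], after[rel][0])
            np.testing.assert_array_equal(before[rel][1], after[rel][1])

    def test_empty_schema_rejected(self):
        with pytest.raises(ValueError):
            PointerParams(d_h=4, schema=[], rng=np.random.default_rng(0))


class TestExtractTriples:
    def _force(self, text, head_spans, tails_by_head, schema):
        """Build an M2/params pair whose pointer probabilities binarise to
        the given gold labels: one-hot M2 rows and huge weights."""
        n = len(text)
        d = n  # one-hot positions
        params = PointerParams(d_h=d, schema=schema,
                               rng=np.random.default_rng(0))
        m2 = np.eye(n)
        big = 50.0
        params.head_w.data[:] = -big
        params.head_b.data[:] = 0.0
        for (s, e) in head_spans:
            params.head_w.data[s, 0] = big
            params.head_w.data[e - 1, 1] = big
        params.tail_w_start.data[:] = -big
        params.tail_w_end.data[:] = -big
        params.tail_b_start.data[:] = -big
        params.tail_b_end.data[:] = -big
        # tail scoring sees M2_i + v_sub; v_sub is the mean of one-hot rows
        # over the head span, so weight rows inside the head span can gate
        # per-head behaviour. Here all heads share tails per relation.
        for rel, spans in tails_by_head.items():
            j = schema.index(rel)
            for (s, e) in spans:
                params.tail_w_start.data[s, j] = 3 * big
                params.tail_w_end.data[e - 1, j] = 3 * big
        return m2, params

    def test_overlap_worked_example(self):
        """One head carrying two attribute tails yields two triples that
        share the head span — the single-entity-overlap pattern."""
        text = "Zhongmai 159, 827 g/L unit weight, crude protein content 14.8%."
        schema = ["Unit weight", "Crude protein content"]
        m2, params = self._force(
            text, head_spans=[(0, 12)],
            tails_by_head={"Unit weight": [(14, 21)],
                           "Crude protein content": [(57, 62)]},
            schema=schema)
        triples = extract_triples(text, m2, params, 0.5)
        assert len(triples) == 2
        heads = {t.head.text for t in triples}
        assert heads == {"Zhongmai 159"}
        got = {(t.relation, t.tail.text) for t in triples}
        assert got == {("Unit weight", "827 g/L"),
                       ("Crude protein content", "14.8%")}

    def test_no_heads_no_triples(self):
        text = "nothing here"
        schema = ["r"]
        params = PointerParams(d_h=3, schema=schema,
                               rng=np.random.default_rng(0))
        params.head_w.data[:] = 0.0
        params.head_b.data[:] = -50.0
        m2 = np.zeros((len(text), 3))
        assert extract_triples(text, m2, params, 0.5) == set()

    def test_schema_mismatch_rejected(self, params):
        with pytest.raises(ValueError):
            extract_triples("abc", np.zeros((3, 8)), params, 0.5,
                            schema=["other"])


def test_triple_is_hashable_and_offset_compared():
    a = Triple(Span(0, 2, "ab"), "r", Span(3, 5, "cd"))
    b = Triple(Span(0, 2, ""), "r", Span(3, 5, ""))
    assert a == b and len({a, b}) == 1
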