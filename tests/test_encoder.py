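"""Fusion attention, the fused encoder stack, and bidirectional encoding."""

import numpy as np
import pytest

from wheatrex.encoder import (CharVocab, DCWFEncoder, EncoderConfig,
                              word_attention_fuse)
from wheatrex.lexicon import WordVectorTable, match_candidate_words
from wheatrex.nn import Tensor, no_grad
from wheatrex.nn.layers import BiLSTM


def small_config(**kw):
    base = dict(layers=2, fusion_layer=1, hidden_dim=16, word_dim=6, m=3,
                heads=2, max_len=40, seed=0)
    base.update(kw)
    return EncoderConfig(**base)


@pytest.fixture
def table():
    rng = np.random.default_rng(9)
    words = ["g/L", "ab", "abc", "he", "eat", "wheat"]
    return WordVectorTable(entries={w: rng.normal(size=6) for w in words},
                           word_dim=6)


def build(config=None, texts=("wheat abc g/L",)):
    config = config or small_config()
    return DCWFEncoder(config, CharVocab.build(list(texts)))


class TestWordAttentionFuse:
    def test_identical_candidates_give_uniform_weights(self):
        """Equal logits -> softmax 1/m each; the fused vector is z + v."""
        z = np.array([1.0, -2.0, 0.5])
        v = np.array([0.3, 0.1, -0.7])
        cands = np.stack([v, v, v, v])
        fused, weights = word_attention_fuse(z, cands, np.eye(3))
        np.testing.assert_allclose(weights, 0.25)
        np.testing.assert_allclose(fused, z + v)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            z = rng.normal(size=5)
            c = rng.normal(size=(4, 5))
            w = rng.normal(size=(5, 5))
            _, weights = word_attention_fuse(z, c, w)
            assert weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_two_candidate_scalar_oracle(self):
        """d_h=2, m=2, identity bilinear matrix, z=(1,0), candidates (1,0)
        and (0,1): logits (1,0), weights (e/(e+1), 1/(e+1))."""
        z = np.array([1.0, 0.0])
        cands = np.array([[1.0, 0.0], [0.0, 1.0]])
        fused, weights = word_attention_fuse(z, cands, np.eye(2))
        e = np.e
        np.testing.assert_allclose(weights, [e / (e + 1), 1 / (e + 1)])
        expected = z + weights[0] * cands[0] + weights[1] * cands[1]
        np.testing.assert_allclose(fused, expected)

    def test_random_inputs_match_equation_oracle(self):
        """a = softmax(z W c^T); c~ = sum a_j c_j; h~ = z + c~."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            m, d = int(rng.integers(1, 6)), int(rng.integers(2, 8))
            z = rng.normal(size=d)
            c = rng.normal(size=(m, d))
            w = rng.normal(size=(d, d))
            fused, weights = word_attention_fuse(z, c, w)
            logits = np.array([z @ w @ c[j] for j in range(m)])
            exp = np.exp(logits - logits.max())
            a = exp / exp.sum()
            np.testing.assert_allclose(weights, a, atol=1e-12)
            np.testing.assert_allclose(fused, z + a @ c, atol=1e-12)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            word_attention_fuse(np.array([np.inf, 0.0]), np.zeros((2, 2)),
                                np.eye(2))


class TestConfig:
    def test_fusion_layer_bounds(self):
        with pytest.raises(ValueError):
            small_config(layers=2, fusion_layer=3)
        with pytest.raises(ValueError):
            small_config(fusion_layer=0)

    def test_fusion_position_grid_accepted(self):
        """The experimental grid N in {1,3,6,9,12} builds without error."""
        for n in (1, 3, 6, 9, 12):
            cfg = EncoderConfig(layers=12, fusion_layer=n, hidden_dim=16,
                                word_dim=6, heads=2, max_len=16)
            assert cfg.fusion_layer == n

    def test_default_fusion_position_is_one(self):
        assert EncoderConfig().fusion_layer == 1

    def test_full_scale_preset_values(self):
        cfg = EncoderConfig.full_scale_preset()
        assert (cfg.layers, cfg.hidden_dim, cfg.word_dim, cfg.m,
                cfg.max_len) == (12, 768, 200, 3, 256)

    def test_roundtrip_via_dict(self):
        cfg = small_config(mask_pad=True)
        assert EncoderConfig.from_dict(cfg.to_dict()) == cfg


class TestDCWFEForward:
    def test_shape_contract(self, table):
        enc = build()
        text = "wheat abc"
        matches = match_candidate_words(text, table, m=3)
        m1, m2 = enc.encode(text, matches)
        assert m1.shape == (len(text), 16)
        assert m2.shape == (len(text), 16)
        assert np.all(np.isfinite(m1)) and np.all(np.isfinite(m2))

    def test_empty_sentence_rejected(self, table):
        enc = build()
        with pytest.raises(ValueError):
            enc.embed("")

    def test_truncation_at_max_len(self, table):
        enc = build(small_config(max_len=5))
        text = "wheat abc g/L"
        matches = match_candidate_words(text, table, m=3)
        m1, _ = enc.encode(text, matches)
        assert m1.shape[0] == 5

    def test_deterministic_from_seed(self, table):
        text = "wheat abc"
        matches = match_candidate_words(text, table, m=3)
        out1 = build().encode(text, matches)
        out2 = build().encode(text, matches)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_fusion_at_top_layer_equals_encode_then_fuse_once(self, table):
        """With N = L the deep path degenerates to the shallow scheme: run
        all L layers unfused, then fuse once on the final states."""
        config = small_config(layers=3, fusion_layer=3)
        enc = build(config)
        text = "wheat abc g/L"
        matches = match_candidate_words(text, table, m=3)
        m1_deep = enc.dcwfe_forward(text, matches).data

        with no_grad():
            x = enc.embed(text)
            for layer in enc.layers:
                x = layer(x)
            shallow = enc.fuse_states(x, matches).data
        np.testing.assert_allclose(m1_deep, shallow, atol=1e-5)

    def test_fusion_changes_states_and_ablation_disables_it(self, table):
        text = "wheat abc"
        matches = match_candidate_words(text, table, m=3)
        on = build().encode(text, matches)[0]
        off = build(small_config(use_fusion=False)).encode(text, matches)[0]
        assert not np.allclose(on, off)

    def test_pad_only_positions_unchanged_by_masked_fusion(self):
        """With mask_pad, a position whose slots are all PAD gets a zero
        fusion increment (uniform weights over zero vectors)."""
        table = WordVectorTable(entries={}, word_dim=6)
        config = small_config(mask_pad=True)
        enc = build(config)
        text = "xyz"
        matches = match_candidate_words(text, table, m=3)
        with no_grad():
            x = enc.embed(text)
            fused = enc.fuse_states(x, matches)
        np.testing.assert_allclose(fused.data, x.data, atol=1e-12)


class TestBiLSTM:
    def test_length_and_width_preserved(self, table):
        enc = build()
        text = "wheat abc"
        matches = match_candidate_words(text, table, m=3)
        m1, m2 = enc.encode(text, matches)
        assert m2.shape == m1.shape

    def test_ablation_passes_m1_through(self, table):
        enc = build(small_config(use_bilstm=False))
        text = "wheat"
        matches = match_candidate_words(text, table, m=3)
        m1, m2 = enc.encode(text, matches)
        np.testing.assert_array_equal(m1, m2)

    def test_direction_symmetry(self):
        """Swapping the two directional LSTMs and reversing the input
        reverses the output with its halves exchanged."""
        rng = np.random.default_rng(4)
        net = BiLSTM(5, 8, rng)
        swapped = BiLSTM(5, 8, np.random.default_rng(99))
        swapped.fwd, swapped.bwd = net.bwd, net.fwd
        x = rng.normal(size=(7, 5))
        with no_grad():
            out = net(Tensor(x)).data
            out_swapped = swapped(Tensor(x[::-1].copy())).data
        flipped = out_swapped[::-1]
        np.testing.assert_allclose(out[:, :4], flipped[:, 4:], atol=1e-12)
        np.testing.assert_allclose(out[:, 4:], flipped[:, :4], atol=1e-12)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            BiLSTM(4, 5, np.random.default_rng(0))
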