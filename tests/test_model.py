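import numpy as np
import pytest

import opreport as op
from opreport.model import (
    ModelConfig,
    ModelConfigError,
    ModelParams,
    assemble_pattern_input,
    check_vocab_compatible,
    decode_step,
    encode_sequence,
    generate_report,
    generate_sentence,
    init_decoder_state,
    init_model,
    loss_and_grads,
)
from opreport.tokenizer import BLOCK_SEP, KW_MARK


def _small_cfg(vocab_size=30, **kw):
    defaults = dict(vocab_size=vocab_size, embedding_size=8, hidden_size=6,
                    max_decode_length=12, seed=5)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestInitModel:
    def test_same_seed_identical(self):
        cfg = _small_cfg()
        p1, p2 = init_model(cfg), init_model(cfg)
        assert set(p1.arrays) == set(p2.arrays)
        for k in p1.arrays:
            np.testing.assert_array_equal(p1.arrays[k], p2.arrays[k])

    def test_different_seed_differs(self):
        cfg = _small_cfg()
        p1 = init_model(cfg, seed=1)
        p2 = init_model(cfg, seed=2)
        assert not np.array_equal(p1.arrays["emb"], p2.arrays["emb"])

    def test_vocab_mismatch_rejected(self, tiny_vocab):
        cfg = _small_cfg(vocab_size=tiny_vocab.size + 1)
        with pytest.raises(ModelConfigError):
            check_vocab_compatible(cfg, tiny_vocab)

    def test_shapes(self):
        cfg = _small_cfg()
        p = init_model(cfg)
        assert p.arrays["emb"].shape == (30, 8)
        assert p.arrays["enc_l0_f_Wx"].shape == (8, 24)
        assert p.arrays["enc_l1_f_Wx"].shape == (12, 24)
        assert p.arrays["out_W"].shape == (18, 30)
        assert p.check_finite()

    def test_checkpoint_round_trip(self, tmp_path):
        p = init_model(_small_cfg())
        path = tmp_path / "ckpt.npz"
        p.save(path)
        loaded = ModelParams.load(path)
        assert loaded.config == p.config
        for k in p.arrays:
            np.testing.assert_array_equal(loaded.arrays[k], p.arrays[k])


class TestEncodeSequence:
    def test_one_latent_per_position(self):
        p = init_model(_small_cfg())
        lat = encode_sequence(p, [4, 9, 11, 2])
        assert lat.shape == (4, 12)  # 2 * hidden per position
        assert np.all(np.isfinite(lat))

    def test_deterministic(self):
        p = init_model(_small_cfg())
        l1 = encode_sequence(p, [5, 6, 7])
        l2 = encode_sequence(p, [5, 6, 7])
        np.testing.assert_array_equal(l1, l2)

    def test_order_sensitivity(self):
        p = init_model(_small_cfg())
        l1 = encode_sequence(p, [4, 9, 11])
        l2 = encode_sequence(p, [11, 9, 4])
        assert not np.allclose(l1, l2)

    def test_empty_input_rejected(self):
        p = init_model(_small_cfg())
        with pytest.raises(ValueError):
            encode_sequence(p, [])

    def test_out_of_range_id_rejected(self):
        p = init_model(_small_cfg())
        with pytest.raises(ValueError):
            encode_sequence(p, [29, 30])


class TestDecodeStep:
    def test_distribution_normalized(self):
        p = init_model(_small_cfg())
        state, lat = init_decoder_state(p, [4, 5, 6])
        probs, state2, attn = decode_step(p, state, 2, lat)
        assert probs.shape == (30,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_attention_weights_normalized(self):
        p = init_model(_small_cfg())
        state, lat = init_decoder_state(p, [4, 5, 6, 7, 8])
        for tok in (2, 5, 9):
            _, state, attn = decode_step(p, state, tok, lat)
            assert attn.shape == (5,)
            assert np.all(attn >= 0)
            assert attn.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_position_attention_is_identity(self):
        # with one latent position the context vector must equal that latent
        p = init_model(_small_cfg())
        state, lat = init_decoder_state(p, [7])
        _, _, attn = decode_step(p, state, 2, lat)
        assert attn.shape == (1,)
        assert attn[0] == pytest.approx(1.0, abs=1e-6)


class TestGenerateSentence:
    def test_greedy_deterministic(self):
        p = init_model(_small_cfg())
        ids = [4, 9, 5, 3]
        assert generate_sentence(p, ids) == generate_sentence(p, ids)

    def test_max_decode_length_respected(self):
        p = init_model(_small_cfg(max_decode_length=5))
        out = generate_sentence(p, [4, 9, 5])
        assert len(out) <= 5

    def test_beam_deterministic_and_bounded(self):
        p = init_model(_small_cfg(max_decode_length=6))
        out1 = generate_sentence(p, [4, 9], mode="beam", beam_width=3)
        out2 = generate_sentence(p, [4, 9], mode="beam", beam_width=3)
        assert out1 == out2
        assert len(out1) <= 6

    def test_unknown_mode_rejected(self):
        p = init_model(_small_cfg())
        with pytest.raises(ValueError):
            generate_sentence(p, [4], mode="sampling")


class TestPatternInput:
    def test_layout_markers(self, tiny_vocab):
        ids = assemble_pattern_input(tiny_vocab, ["alpha", "beta"], "ein satz")
        assert ids[0] == tiny_vocab.piece_id(KW_MARK)
        assert ids.count(tiny_vocab.piece_id(KW_MARK)) == 1
        assert ids.count(tiny_vocab.piece_id(BLOCK_SEP)) == 1
        assert ids[-1] == tiny_vocab.eos_id

    def test_report_start_placeholder(self, tiny_vocab):
        ids = assemble_pattern_input(tiny_vocab, ["kw"], op.REPORT_START)
        assert tiny_vocab.piece_id(op.REPORT_START) in ids


class TestGenerateReport:
    def test_one_sentence_per_group(self, tiny_vocab):
        cfg = _small_cfg(vocab_size=tiny_vocab.size)
        p = init_model(cfg)
        report = generate_report(p, tiny_vocab, [["a"], ["b", "c"], ["d"]])
        assert len(report.sentences) == 3
        assert report.sentences[1].keywords == ["b", "c"]

    def test_deterministic(self, tiny_vocab):
        cfg = _small_cfg(vocab_size=tiny_vocab.size)
        p = init_model(cfg)
        groups = [["a", "b"], ["c"]]
        r1 = generate_report(p, tiny_vocab, groups)
        r2 = generate_report(p, tiny_vocab, groups)
        assert [s.text for s in r1.sentences] == [s.text for s in r2.sentences]

    def test_empty_group_names_index(self, tiny_vocab):
        cfg = _small_cfg(vocab_size=tiny_vocab.size)
        p = init_model(cfg)
        with pytest.raises(ValueError, match="group 1"):
            generate_report(p, tiny_vocab, [["a"], []])


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central-difference check of every parameter family (float64)."""
        rng = np.random.default_rng(0)
        cfg = ModelConfig(vocab_size=20, embedding_size=5, hidden_size=4, seed=3)
        params = init_model(cfg, dtype=np.float64)
        B, Tx, Ty = 3, 6, 5
        X = rng.integers(0, 20, size=(B, Tx))
        Mx = np.ones((B, Tx)); Mx[0, 4:] = 0
        Yin = rng.integers(0, 20, size=(B, Ty))
        Yout = rng.integers(0, 20, size=(B, Ty))
        My = np.ones((B, Ty)); My[2, 3:] = 0
        loss, grads = loss_and_grads(params, X, Mx, Yin, Yout, My)
        assert np.isfinite(loss)
        eps = 1e-6
        for name, arr in params.arrays.items():
            flat = arr.ravel()
            g = grads[name].ravel()
            big = np.where(np.abs(g) > 1e-4)[0]
            if big.size == 0:
                continue
            for i in rng.choice(big, size=min(4, big.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = loss_and_grads(params, X, Mx, Yin, Yout, My, want_grads=False)
                flat[i] = orig - eps
                lm, _ = loss_and_grads(params, X, Mx, Yin, Yout, My, want_grads=False)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[i], rel=1e-4, abs=1e-8), name

    def test_padding_does_not_change_loss(self):
        """Extending sequences with masked padding leaves the loss invariant."""
        rng = np.random.default_rng(1)
        cfg = ModelConfig(vocab_size=20, embedding_size=5, hidden_size=4, seed=3)
        params = init_model(cfg, dtype=np.float64)
        X = rng.integers(1, 20, size=(2, 4))
        Yin = rng.integers(1, 20, size=(2, 3))
        Yout = rng.integers(1, 20, size=(2, 3))
        ones = np.ones((2, 4)), np.ones((2, 3))
        loss1, _ = loss_and_grads(params, X, ones[0], Yin, Yout, ones[1],
                                  want_grads=False)
        Xp = np.concatenate([X, np.zeros((2, 2), dtype=np.int64)], axis=1)
        Mxp = np.concatenate([ones[0], np.zeros((2, 2))], axis=1)
        Yinp = np.concatenate([Yin, np.zeros((2, 1), dtype=np.int64)], axis=1)
        Youtp = np.concatenate([Yout, np.zeros((2, 1), dtype=np.int64)], axis=1)
        Myp = np.concatenate([ones[1], np.zeros((2, 1))], axis=1)
        loss2, _ = loss_and_grads(params, Xp, Mxp, Yinp, Youtp, Myp,
                                  want_grads=False)
        assert loss2 == pytest.approx(loss1, rel=1e-12)
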