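"""Attention primitives against scalar-loop oracles, and network contracts."""

import math

import numpy as np
import pytest

import dtifusion as dt
from dtifusion import autograd as ag
from dtifusion.model import (
    AttentionWeights,
    ConfigError,
    FeedForwardWeights,
    ModelConfig,
    MultiViewDTI,
    feed_forward,
    multi_head_attention,
    scaled_dot_attention,
)
from dtifusion.vocab import Vocabulary

from conftest import tiny_model_config


@pytest.fixture(autouse=True)
def _float64():
    # the oracle comparisons below are at 1e-5/1e-6 tolerances
    with ag.use_dtype(np.float64):
        yield


def attention_oracle(q, k, v):
    """Scalar-loop scaled dot-product attention on 2-D matrices."""
    Lq, d_k = q.shape
    Lk = k.shape[0]
    out = np.zeros((Lq, v.shape[1]))
    for i in range(Lq):
        logits = [sum(q[i, t] * k[j, t] for t in range(d_k)) / math.sqrt(d_k) for j in range(Lk)]
        mx = max(logits)
        weights = [math.exp(l - mx) for l in logits]
        z = sum(weights)
        weights = [w / z for w in weights]
        for c in range(v.shape[1]):
            out[i, c] = sum(weights[j] * v[j, c] for j in range(Lk))
    return out


class TestScaledDotAttention:
    def test_single_position_returns_v(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(1, 4))
        k = rng.normal(size=(1, 4))
        v = rng.normal(size=(1, 3))
        np.testing.assert_allclose(scaled_dot_attention(q, k, v), v, atol=1e-12)

    def test_identical_keys_average_v(self):
        q = np.array([[1.0, 2.0]])
        k = np.array([[0.3, -0.1], [0.3, -0.1]])
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(
            scaled_dot_attention(q, k, v), [[0.5, 0.5]], atol=1e-12
        )

    @pytest.mark.parametrize("d_k", [2, 4, 8])
    def test_matches_scalar_oracle_across_key_dims(self, d_k):
        rng = np.random.default_rng(d_k)
        q = rng.normal(size=(5, d_k))
        k = rng.normal(size=(6, d_k))
        v = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            scaled_dot_attention(q, k, v), attention_oracle(q, k, v), atol=1e-10
        )

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            q = rng.normal(size=(4, 3))
            k = rng.normal(size=(5, 3))
            weights = ag.softmax(
                ag.as_tensor(q * (1 / np.sqrt(3))) @ ag.as_tensor(k.T), axis=-1
            ).data
            np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
            assert (weights >= 0).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 2)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_attention(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 4))
        eye = ag.Tensor(np.eye(4))
        w = AttentionWeights(w_q=eye, w_k=eye, w_v=eye, w_o=eye, n_heads=1)
        np.testing.assert_allclose(
            multi_head_attention(x, w), scaled_dot_attention(x, x, x), atol=1e-12
        )

    def test_zero_input_zero_output(self):
        rng = np.random.default_rng(2)
        mats = {n: ag.Tensor(rng.normal(size=(6, 6))) for n in ("w_q", "w_k", "w_v", "w_o")}
        w = AttentionWeights(n_heads=2, **mats)
        out = multi_head_attention(np.zeros((4, 6)), w)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_head_split_shapes(self):
        rng = np.random.default_rng(3)
        mats = {n: ag.Tensor(rng.normal(size=(20, 20))) for n in ("w_q", "w_k", "w_v", "w_o")}
        w = AttentionWeights(n_heads=5, **mats)
        assert w.d_k == 4
        out = multi_head_attention(rng.normal(size=(9, 20)), w)
        assert out.shape == (9, 20)

    def test_matches_per_head_oracle(self):
        rng = np.random.default_rng(4)
        d_model, n_heads = 6, 3
        x = rng.normal(size=(5, d_model))
        mats = {n: rng.normal(size=(d_model, d_model)) for n in ("w_q", "w_k", "w_v", "w_o")}
        w = AttentionWeights(n_heads=n_heads,
                             **{n: ag.Tensor(m) for n, m in mats.items()})
        d_k = d_model // n_heads
        heads = []
        for h in range(n_heads):
            sl = slice(h * d_k, (h + 1) * d_k)
            heads.append(attention_oracle(x @ mats["w_q"][:, sl],
                                          x @ mats["w_k"][:, sl],
                                          x @ mats["w_v"][:, sl]))
        expected = np.concatenate(heads, axis=1) @ mats["w_o"]
        np.testing.assert_allclose(multi_head_attention(x, w), expected, atol=1e-10)

    def test_indivisible_heads_rejected(self):
        rng = np.random.default_rng(5)
        mats = {n: ag.Tensor(rng.normal(size=(6, 6))) for n in ("w_q", "w_k", "w_v", "w_o")}
        w = AttentionWeights(n_heads=4, **mats)
        with pytest.raises(ConfigError):
            multi_head_attention(np.zeros((3, 6)), w)


class TestFeedForward:
    def make_weights(self, rng, d_in=4, d_hidden=6, d_out=4, zero_bias=False):
        return FeedForwardWeights(
            w1=ag.Tensor(rng.normal(size=(d_in, d_hidden))),
            b1=ag.Tensor(np.zeros(d_hidden) if zero_bias else rng.normal(size=d_hidden)),
            w2=ag.Tensor(rng.normal(size=(d_hidden, d_out))),
            b2=ag.Tensor(np.zeros(d_out) if zero_bias else rng.normal(size=d_out)),
        )

    def test_zero_input_zero_bias_gives_zero(self):
        w = self.make_weights(np.random.default_rng(0), zero_bias=True)
        np.testing.assert_allclose(feed_forward(np.zeros((3, 4)), w), 0.0, atol=1e-12)

    def test_all_negative_preactivations_give_b2(self):
        rng = np.random.default_rng(1)
        w = self.make_weights(rng)
        w.b1.data = -np.full(6, 100.0)  # drives every hidden unit below zero
        out = feed_forward(rng.normal(size=(2, 4)), w)
        np.testing.assert_allclose(out, np.tile(w.b2.data, (2, 1)), atol=1e-12)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(2)
        w = self.make_weights(rng)
        x = rng.normal(size=(3, 4))
        expected = np.zeros((3, 4))
        for i in range(3):
            hidden = [max(0.0, sum(x[i, a] * w.w1.data[a, h] for a in range(4)) + w.b1.data[h])
                      for h in range(6)]
            for o in range(4):
                expected[i, o] = sum(hidden[h] * w.w2.data[h, o] for h in range(6)) + w.b2.data[o]
        np.testing.assert_allclose(feed_forward(x, w), expected, atol=1e-10)


def build_tiny_model(**overrides):
    cfg = tiny_model_config(**overrides)
    return MultiViewDTI(cfg, protein_vocab_rows=27, drug_vocab_rows=12), cfg


def random_batch(rng, cfg, n=4, protein_len=20, drug_len=10, drug_high=11):
    prot = np.zeros((n, cfg.protein_length), dtype=np.int64)
    drug = np.zeros((n, cfg.drug_length), dtype=np.int64)
    prot[:, :protein_len] = rng.integers(1, 27, size=(n, protein_len))
    drug[:, :drug_len] = rng.integers(1, drug_high, size=(n, drug_len))
    fp = (rng.random((n, 2048)) < 0.05).astype(np.uint8)
    return prot, drug, fp


class TestForward:
    def test_probabilities_strictly_inside_unit_interval(self):
        model, cfg = build_tiny_model()
        prot, drug, fp = random_batch(np.random.default_rng(0), cfg)
        p = model.forward(prot, drug, fp).data
        assert p.shape == (4,)
        assert ((p > 0) & (p < 1)).all()

    def test_deterministic_given_weights(self):
        model, cfg = build_tiny_model()
        prot, drug, fp = random_batch(np.random.default_rng(1), cfg)
        p1 = model.forward(prot, drug, fp).data
        p2 = model.forward(prot, drug, fp).data
        np.testing.assert_array_equal(p1, p2)

    def test_padding_invariance(self):
        # same real tokens, longer pad tail => identical output
        model, cfg = build_tiny_model()
        longer, _ = build_tiny_model(protein_length=96, drug_length=60)
        longer.load_state_dict(model.state_dict())
        prot, drug, fp = random_batch(np.random.default_rng(2), cfg, protein_len=18, drug_len=8)
        p1 = model.forward(prot, drug, fp).data
        prot2 = np.zeros((4, 96), dtype=np.int64)
        prot2[:, : cfg.protein_length] = prot
        drug2 = np.zeros((4, 60), dtype=np.int64)
        drug2[:, : cfg.drug_length] = drug
        p2 = longer.forward(prot2, drug2, fp).data
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_dropout_only_active_in_training(self):
        model, cfg = build_tiny_model(embedding_dropout_rate=0.5)
        prot, drug, fp = random_batch(np.random.default_rng(3), cfg)
        rng = np.random.default_rng(0)
        p_train = model.forward(prot, drug, fp, training=True, rng=rng).data
        p_eval = model.forward(prot, drug, fp).data
        assert not np.allclose(p_train, p_eval)
        np.testing.assert_array_equal(p_eval, model.forward(prot, drug, fp).data)

    @pytest.mark.parametrize("channel", ["protein_cnn", "protein_transformer",
                                         "drug_cnn", "drug_fingerprints"])
    def test_disabling_a_channel_removes_exactly_its_parameters(self, channel):
        full, cfg = build_tiny_model()
        remaining = tuple(c for c in cfg.channels_enabled if c != channel)
        reduced = MultiViewDTI(cfg.with_channels(remaining), 27, 12)
        # the channel's own parameters plus its slice of the first fusion layer
        expected_drop = (full.channel_parameter_count(channel)
                         + cfg.dense_units[0] * cfg.channel_output_width(channel))
        assert full.parameter_count() - reduced.parameter_count() == expected_drop

    def test_at_least_one_channel_per_entity_required(self):
        with pytest.raises(ConfigError):
            tiny_model_config(channels_enabled=("protein_cnn",))
        with pytest.raises(ConfigError):
            tiny_model_config(channels_enabled=("drug_cnn", "drug_fingerprints"))


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, tmp_path):
        model, cfg = build_tiny_model()
        pv = Vocabulary(tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), "protein-kmer")
        dv = dt.build_drug_vocab(["CCO", "c1ccncc1"])
        model2 = MultiViewDTI(cfg, pv.embedding_rows, dv.embedding_rows)
        path = tmp_path / "model.npz"
        dt.save_checkpoint(path, model2, pv, dv)
        loaded = dt.load_checkpoint(path, pv, dv)
        prot, drug, fp = random_batch(np.random.default_rng(4), cfg, drug_high=dv.embedding_rows)
        np.testing.assert_array_equal(
            model2.forward(prot, drug, fp).data, loaded.forward(prot, drug, fp).data
        )

    def test_vocab_mismatch_detected(self, tmp_path):
        model, cfg = build_tiny_model()
        pv = Vocabulary(tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), "protein-kmer")
        dv = dt.build_drug_vocab(["CCO"])
        path = tmp_path / "model.npz"
        dt.save_checkpoint(path, model, pv, dv)
        other = dt.build_drug_vocab(["CCN"])
        with pytest.raises(ConfigError):
            dt.load_checkpoint(path, pv, other)
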