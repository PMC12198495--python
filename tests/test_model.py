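"""Encoder stack: positional table, embedding, BiGRU, attention, FFN, sizes."""

import numpy as np
import pytest
import sympy

from gruner import autograd as ag
from gruner.autograd import Tensor
from gruner.corpus import (
    EncodedBatch,
    PAD_INDEX,
    build_tag_scheme,
    build_vocabulary,
    encode_batch,
)
from gruner.crf import CRFLayer
from gruner.model import (
    BiGRU,
    FeedForward,
    GRUDirection,
    ModelConfig,
    MultiHeadAttention,
    TaggerModel,
    mha_parameter_delta,
    parameter_count,
    positional_encoding,
)


def _random_batch(rng, B=3, T=7, vocab=20, min_len=2):
    lengths = rng.integers(min_len, T + 1, size=B)
    lengths[0] = T  # keep one full-length sentence
    token_ids = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T), dtype=np.int64)
    for b, L in enumerate(lengths):
        token_ids[b, :L] = rng.integers(2, vocab, size=L)
        mask[b, :L] = 1
    tag_ids = np.zeros((B, T), dtype=np.int64)
    return EncodedBatch(token_ids, tag_ids, mask, lengths.astype(np.int64))


# -- positional encoding ---------------------------------------------------

def test_positional_row_zero_alternates_zero_one():
    P = positional_encoding(5, 8)
    np.testing.assert_array_equal(P[0], [0, 1, 0, 1, 0, 1, 0, 1])


def test_positional_entries_bounded():
    P = positional_encoding(50, 16)
    assert np.all(P >= -1.0) and np.all(P <= 1.0)


def test_positional_matches_high_precision_closed_form():
    """Every entry equals sin/cos(t * 10000^(-2k/m)) at 50-digit precision."""
    m, T = 8, 12
    P = positional_encoding(T, m)
    for t in range(T):
        for i in range(m):
            k = i // 2
            omega = sympy.Float(10000, 50) ** (-sympy.Rational(2 * k, m))
            fn = sympy.sin if i % 2 == 0 else sympy.cos
            expected = float(sympy.N(fn(t * omega), 50))
            assert abs(P[t, i] - expected) < 1e-9, (t, i)


def test_positional_spot_values():
    P = positional_encoding(4, 8)
    assert abs(P[1, 0] - np.sin(1.0)) < 1e-12
    assert abs(P[3, 4] - np.sin(3.0 * 10000.0 ** (-4.0 / 8.0))) < 1e-12


def test_positional_rejects_odd_dimension():
    with pytest.raises(ValueError):
        positional_encoding(10, 7)


# -- embedding + position --------------------------------------------------

@pytest.fixture()
def small_model(rng):
    cfg = ModelConfig(m=8, h=2, d_ff=12, dropout_rate=0.2, max_len=7)
    return TaggerModel(cfg, vocab_size=20, tagset_size=5, rng=rng)


def test_pad_position_embeds_to_positional_row(small_model, rng):
    batch = _random_batch(rng)
    x = small_model.embed_and_position(batch).data
    P = small_model.pos_table
    for b in range(batch.batch_size):
        for t in range(batch.padded_length):
            if batch.mask[b, t] == 0:
                np.testing.assert_allclose(x[b, t], P[t], atol=0)


def test_embed_and_position_deterministic(small_model, rng):
    batch = _random_batch(rng)
    a = small_model.embed_and_position(batch).data
    b = small_model.embed_and_position(batch).data
    np.testing.assert_array_equal(a, b)


def test_embed_rejects_out_of_range_ids(small_model, rng):
    batch = _random_batch(rng)
    batch.token_ids[0, 0] = 99
    with pytest.raises(ValueError, match="out of range"):
        small_model.embed_and_position(batch)


# -- BiGRU -----------------------------------------------------------------

def test_bigru_masked_positions_cannot_influence_real_ones(rng):
    gru = BiGRU(4, 3, rng, "g")
    mask = np.array([[1, 1, 1, 0, 0]])
    x1 = rng.normal(size=(1, 5, 4))
    x2 = x1.copy()
    x2[0, 3:] = rng.normal(size=(2, 4)) * 50  # perturb only padded tail
    out1 = gru(Tensor(x1), mask).data
    out2 = gru(Tensor(x2), mask).data
    np.testing.assert_allclose(out1[0, :3], out2[0, :3], atol=1e-12)


def test_bigru_single_token_is_one_step_each_direction(rng):
    gru = BiGRU(4, 3, rng, "g")
    x = rng.normal(size=(1, 1, 4))
    out = gru(Tensor(x), np.ones((1, 1), dtype=np.int64)).data
    h0 = Tensor(np.zeros((1, 3)))
    fwd = gru.fwd.step(Tensor(x[:, 0]), h0).data
    bwd = gru.bwd.step(Tensor(x[:, 0]), h0).data
    np.testing.assert_allclose(out[0, 0], np.concatenate([fwd[0], bwd[0]]), atol=1e-12)


def test_bigru_reversal_symmetry(rng):
    """Reversing the sequence and swapping direction parameter sets mirrors
    the output: forward-on-reversed equals reversed backward-on-original."""
    a = GRUDirection(4, 3, rng, "a")
    b = GRUDirection(4, 3, rng, "b")
    for p, q in zip(a.parameters(), b.parameters()):
        q.data = p.data.copy()  # identical parameters, used as fwd vs bwd
    x = rng.normal(size=(2, 6, 4))
    mask = np.ones((2, 6), dtype=np.int64)
    fwd_rev = a.run(Tensor(x[:, ::-1].copy()), mask, reverse=False).data
    bwd = b.run(Tensor(x), mask, reverse=True).data
    np.testing.assert_allclose(fwd_rev[:, ::-1], bwd, atol=1e-12)


# -- multi-head attention --------------------------------------------------

def test_attention_single_position_weight_is_one(rng):
    cfg = ModelConfig(m=8, h=2, d_ff=12, max_len=4)
    mha = MultiHeadAttention(cfg, rng, "mha")
    x = Tensor(rng.normal(size=(1, 4, 8)))
    mask = np.array([[1, 0, 0, 0]])
    _, w = mha(x, x, x, mask)
    np.testing.assert_allclose(w[0, :, 0, 0], 1.0, atol=1e-12)
    np.testing.assert_allclose(w[0, :, 0, 1:], 0.0, atol=0)


def test_attention_uniform_when_keys_identical(rng):
    cfg = ModelConfig(m=8, h=2, d_ff=12, max_len=5)
    mha = MultiHeadAttention(cfg, rng, "mha")
    row = rng.normal(size=8)
    x = Tensor(np.tile(row, (1, 5, 1)))
    mask = np.array([[1, 1, 1, 1, 0]])
    _, w = mha(x, x, x, mask)
    np.testing.assert_allclose(w[0, :, :, :4], 0.25, atol=1e-12)
    np.testing.assert_allclose(w[0, :, :, 4], 0.0, atol=0)


def test_attention_rows_normalize_with_zero_mass_on_padding(rng):
    cfg = ModelConfig(m=8, h=4, d_ff=12, max_len=7)
    mha = MultiHeadAttention(cfg, rng, "mha")
    batch_mask = np.array([[1] * 7, [1] * 3 + [0] * 4])
    x = Tensor(rng.normal(size=(2, 7, 8)))
    _, w = mha(x, x, x, batch_mask)
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)
    assert np.all(w[1, :, :, 3:] == 0.0)


def test_two_token_attention_matches_hand_rolled_softmax(rng):
    """With identity projections the block reduces to softmax(QK^T/sqrt(dk)) V."""
    cfg = ModelConfig(m=4, h=1, d_ff=8, max_len=2)
    mha = MultiHeadAttention(cfg, rng, "mha")
    eye = np.eye(4)
    for lin in (mha.W_q, mha.W_k, mha.W_v, mha.W_o):
        lin.W.data = eye.copy()
        lin.b.data = np.zeros(4)
    x = rng.normal(size=(1, 2, 4))
    _, w = mha(Tensor(x), Tensor(x), Tensor(x), np.ones((1, 2), dtype=np.int64))
    scores = x[0] @ x[0].T / np.sqrt(4.0)
    expected = np.exp(scores - scores.max(axis=1, keepdims=True))
    expected /= expected.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(w[0, 0], expected, atol=1e-12)


def test_config_rejects_indivisible_heads():
    with pytest.raises(ValueError):
        ModelConfig(m=10, h=4)


# -- feed-forward ----------------------------------------------------------

def test_ffn_eval_mode_deterministic(rng):
    cfg = ModelConfig(m=8, h=2, d_ff=12, max_len=4)
    ffn = FeedForward(cfg, rng, "ffn")
    x = Tensor(rng.normal(size=(2, 4, 8)))
    np.testing.assert_array_equal(ffn(x).data, ffn(x).data)


def test_ffn_zero_weights_reduce_to_layernorm_of_input(rng):
    cfg = ModelConfig(m=8, h=2, d_ff=12, max_len=4)
    ffn = FeedForward(cfg, rng, "ffn")
    for p in (ffn.h1.W, ffn.h1.b, ffn.h2.W, ffn.h2.b):
        p.data[...] = 0.0
    x = Tensor(rng.normal(size=(1, 3, 8)))
    got = ffn(x).data
    expected = ag.layer_norm(x, ffn.ln_gain, ffn.ln_bias).data
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_ffn_relu_kills_negative_preactivations(rng):
    cfg = ModelConfig(m=8, h=2, d_ff=12, max_len=4)
    ffn = FeedForward(cfg, rng, "ffn")
    ffn.h1.W.data[...] = 0.0
    ffn.h1.b.data[...] = -1.0  # all h1 preactivations negative
    x = Tensor(rng.normal(size=(1, 3, 8)))
    h1 = ag.relu(ffn.h1(x)).data
    assert np.all(h1 == 0.0)


# -- full stack ------------------------------------------------------------

def test_emissions_shape_and_determinism(small_model, rng):
    batch = _random_batch(rng)
    e1 = small_model.emissions(batch).data
    e2 = small_model.emissions(batch).data
    assert e1.shape == (3, 7, 5)
    np.testing.assert_array_equal(e1, e2)


def test_unmasked_emissions_invariant_to_pad_content(small_model, rng):
    batch = _random_batch(rng)
    e1 = small_model.emissions(batch).data
    tampered = EncodedBatch(
        batch.token_ids.copy(), batch.tag_ids, batch.mask, batch.lengths
    )
    # swap PAD ids for arbitrary real tokens at padded slots
    tampered.token_ids[batch.mask == 0] = 7
    e2 = small_model.emissions(tampered).data
    for b in range(batch.batch_size):
        L = batch.lengths[b]
        np.testing.assert_allclose(e1[b, :L], e2[b, :L], atol=1e-6)


@pytest.mark.parametrize("use_mha", [True, False])
def test_parameter_count_matches_introspection_random_configs(use_mha, rng):
    for _ in range(12):
        m = int(rng.choice([8, 12, 16, 24]))
        h = int(rng.choice([1, 2, 4]))
        cfg = ModelConfig(
            m=m,
            h=h,
            d_ff=int(rng.integers(4, 40)),
            n_encoders=int(rng.integers(1, 3)),
            use_mha=use_mha,
            max_len=int(rng.integers(3, 9)),
        )
        V = int(rng.integers(5, 60))
        K = int(rng.integers(2, 9))
        model = TaggerModel(cfg, V, K, rng)
        crf = CRFLayer(K, rng)
        introspected = model.n_parameters() + sum(p.data.size for p in crf.parameters())
        assert parameter_count(cfg, V, K) == introspected


def test_no_mha_removes_exactly_the_attention_parameters(rng):
    full = ModelConfig(m=16, h=4, d_ff=24, max_len=5)
    ablated = ModelConfig(m=16, h=4, d_ff=24, max_len=5, use_mha=False)
    diff = parameter_count(full, 30, 5) - parameter_count(ablated, 30, 5)
    assert diff == mha_parameter_delta(full)
    assert diff > 0


def test_embedding_contribution_is_vocab_times_m():
    cfg = ModelConfig(m=16, h=4, d_ff=24, max_len=5)
    for V in (10, 31):
        assert parameter_count(cfg, V + 1, 5) - parameter_count(cfg, V, 5) == 16
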