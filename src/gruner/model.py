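"""The emission encoder: embedding + sinusoidal positions -> BiGRU ->
multi-head self-attention (optional) -> position-wise feed-forward ->
linear projection to tag space.

The encoder maps a padded batch of token ids to per-position, per-tag
emission scores consumed by the linear-chain CRF.  Its shape conventions:

* ``m`` — model width (embedding dimension), default 256;
* ``d`` — padded sequence length (``max_len``), fixed to the longest
  training sentence;
* ``h`` — attention heads (default 4), per-head width ``d_k = m / h``;
* ``d_ff`` — feed-forward hidden width, default 512.

The bidirectional GRU uses ``m / 2`` hidden units per direction so the
concatenated output keeps width ``m``, which makes the residual connections
in the attention and feed-forward blocks dimensionally consistent.
Attention scores are scaled by ``1 / sqrt(d_k)`` (a ``1 / d_k`` variant is
selectable via ``attention_scale``).  Padded key positions receive a large
negative bias before the softmax so they carry exactly zero attention mass,
and padded positions never influence loss or decoding (the CRF mask).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor
from .corpus import EncodedBatch, PAD_INDEX

_NEG_BIAS = -1e9  # additive pre-softmax bias on masked keys; exp underflows to 0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``gru_hidden`` defaults to ``m // 2`` (per direction) and must equal it;
    ``use_mha=False`` drops the attention block entirely (the ablation
    variant), leaving BiGRU output to feed the feed-forward block directly.
    """

    m: int = 256
    h: int = 4
    d_ff: int = 512
    gru_hidden: int | None = None
    dropout_rate: float = 0.2
    use_mha: bool = True
    n_encoders: int = 1
    max_len: int | None = None
    attention_scale: str = "sqrt_dk"  # or "dk"

    def __post_init__(self) -> None:
        if self.m < 2 or self.m % 2 != 0:
            raise ValueError(f"m must be even and >= 2, got {self.m}")
        if self.h < 1 or self.m % self.h != 0:
            raise ValueError(f"m={self.m} must be divisible by h={self.h}")
        if self.d_ff < 1:
            raise ValueError("d_ff must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_encoders < 1:
            raise ValueError("n_encoders must be >= 1")
        gh = self.gru_hidden if self.gru_hidden is not None else self.m // 2
        if gh != self.m // 2:
            raise ValueError(
                f"gru_hidden must equal m/2 = {self.m // 2} so the BiGRU "
                f"output keeps width m (got {gh})"
            )
        object.__setattr__(self, "gru_hidden", gh)
        if self.attention_scale not in ("sqrt_dk", "dk"):
            raise ValueError("attention_scale must be 'sqrt_dk' or 'dk'")

    @property
    def head_dim(self) -> int:
        """Per-head query/key/value width d_q = d_k = d_v = m / h."""
        return self.m // self.h

    def with_max_len(self, max_len: int) -> "ModelConfig":
        return replace(self, max_len=max_len)


@dataclass(frozen=True)
class EmissionScores:
    """Per-position tag scores (B x d x n_tags) with the batch mask."""

    scores: np.ndarray
    mask: np.ndarray


def positional_encoding(max_len: int, m: int) -> np.ndarray:
    """Sinusoidal positional table ``P`` of shape ``max_len x m``.

    ``P[t, 2k] = sin(t * w_k)``, ``P[t, 2k+1] = cos(t * w_k)`` with
    ``w_k = 10000 ** (-2k / m)``, so row 0 alternates 0 and 1 and every
    entry lies in [-1, 1].
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if m < 2 or m % 2 != 0:
        raise ValueError(f"embedding dimension must be even and >= 2, got {m}")
    t = np.arange(max_len, dtype=np.float64)[:, None]
    k = np.arange(m // 2, dtype=np.float64)[None, :]
    omega = 10000.0 ** (-2.0 * k / m)
    P = np.empty((max_len, m), dtype=np.float64)
    P[:, 0::2] = np.sin(t * omega)
    P[:, 1::2] = np.cos(t * omega)
    return P


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear:
    """Affine map ``x @ W + b``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        self.W = Parameter(_glorot(rng, n_in, n_out), f"{name}.W")
        self.b = Parameter(np.zeros(n_out), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.W), self.b)

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class GRUDirection:
    """A single-direction GRU scanned over the time axis.

    Gate layout in the fused weight matrices is (reset, update, candidate);
    the candidate path applies the reset gate to the hidden-to-hidden term.
    Hidden-state updates are gated by the batch mask so padded steps leave
    the state untouched — in the backward direction this keeps the padded
    tail from ever influencing real positions.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str):
        self.hidden = hidden
        self.W_x = Parameter(_glorot(rng, n_in, 3 * hidden), f"{name}.W_x")
        self.W_h = Parameter(_glorot(rng, hidden, 3 * hidden), f"{name}.W_h")
        self.b = Parameter(np.zeros(3 * hidden), f"{name}.b")

    def parameters(self) -> list[Parameter]:
        return [self.W_x, self.W_h, self.b]

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        xg = ag.add(ag.matmul(x_t, self.W_x), self.b)
        hg = ag.matmul(h, self.W_h)
        r = ag.sigmoid(ag.add(xg[:, 0:H], hg[:, 0:H]))
        z = ag.sigmoid(ag.add(xg[:, H : 2 * H], hg[:, H : 2 * H]))
        n = ag.tanh(ag.add(xg[:, 2 * H : 3 * H], ag.mul(r, hg[:, 2 * H : 3 * H])))
        return ag.add(ag.mul(ag.sub(1.0, z), n), ag.mul(z, h))

    def run(self, x: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
        """Scan over ``x`` (B x T x n_in); returns B x T x hidden."""
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden)))
        outs: list[Tensor] = [None] * T  # type: ignore[list-item]
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            m_t = mask[:, t : t + 1].astype(np.float64)
            h_new = self.step(x[:, t, :], h)
            h = ag.add(ag.mul(h_new, Tensor(m_t)), ag.mul(h, Tensor(1.0 - m_t)))
            outs[t] = h
        return ag.stack(outs, axis=1)


class BiGRU:
    """Forward and backward GRUs concatenated to width ``2 * hidden``."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, name: str):
        self.fwd = GRUDirection(n_in, hidden, rng, f"{name}.fwd")
        self.bwd = GRUDirection(n_in, hidden, rng, f"{name}.bwd")

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        out_f = self.fwd.run(x, mask, reverse=False)
        out_b = self.bwd.run(x, mask, reverse=True)
        return ag.concat([out_f, out_b], axis=-1)

    def parameters(self) -> list[Parameter]:
        return self.fwd.parameters() + self.bwd.parameters()


class MultiHeadAttention:
    """Scaled dot-product self-attention with ``h`` heads, residual + LayerNorm."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, name: str):
        m = config.m
        self.config = config
        self.W_q = Linear(m, m, rng, f"{name}.W_q")
        self.W_k = Linear(m, m, rng, f"{name}.W_k")
        self.W_v = Linear(m, m, rng, f"{name}.W_v")
        self.W_o = Linear(m, m, rng, f"{name}.W_o")
        self.ln_gain = Parameter(np.ones(m), f"{name}.ln_gain")
        self.ln_bias = Parameter(np.zeros(m), f"{name}.ln_bias")

    def parameters(self) -> list[Parameter]:
        return (
            self.W_q.parameters()
            + self.W_k.parameters()
            + self.W_v.parameters()
            + self.W_o.parameters()
            + [self.ln_gain, self.ln_bias]
        )

    def _split_heads(self, x: Tensor, B: int, T: int) -> Tensor:
        cfg = self.config
        return ag.transpose(
            ag.reshape(x, (B, T, cfg.h, cfg.head_dim)), (0, 2, 1, 3)
        )  # B x h x T x d_k

    def __call__(
        self, q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray
    ) -> tuple[Tensor, np.ndarray]:
        cfg = self.config
        B, T, m = q.shape
        Qh = self._split_heads(self.W_q(q), B, T)
        Kh = self._split_heads(self.W_k(k), B, T)
        Vh = self._split_heads(self.W_v(v), B, T)
        scale = (
            1.0 / np.sqrt(cfg.head_dim)
            if cfg.attention_scale == "sqrt_dk"
            else 1.0 / cfg.head_dim
        )
        scores = ag.mul(ag.matmul(Qh, ag.transpose(Kh, (0, 1, 3, 2))), scale)
        key_bias = _NEG_BIAS * (1.0 - mask.astype(np.float64))[:, None, None, :]
        weights = ag.softmax(ag.add(scores, Tensor(key_bias)), axis=-1)
        ctx = ag.matmul(weights, Vh)  # B x h x T x d_k
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (B, T, m))
        out = self.W_o(ctx)
        out = ag.layer_norm(ag.add(out, q), self.ln_gain, self.ln_bias)
        return out, weights.data.copy()


class FeedForward:
    """Position-wise FFN: ReLU(x W1 + b1) W2 + b2, dropout, residual, LayerNorm."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, name: str):
        self.config = config
        self.h1 = Linear(config.m, config.d_ff, rng, f"{name}.h1")
        self.h2 = Linear(config.d_ff, config.m, rng, f"{name}.h2")
        self.ln_gain = Parameter(np.ones(config.m), f"{name}.ln_gain")
        self.ln_bias = Parameter(np.zeros(config.m), f"{name}.ln_bias")

    def parameters(self) -> list[Parameter]:
        return self.h1.parameters() + self.h2.parameters() + [self.ln_gain, self.ln_bias]

    def __call__(
        self, x: Tensor, training: bool = False, rng: np.random.Generator | None = None
    ) -> Tensor:
        inner = self.h2(ag.relu(self.h1(x)))
        if training and self.config.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode feed_forward needs an rng for dropout")
            inner = ag.dropout(inner, self.config.dropout_rate, rng)
        return ag.layer_norm(ag.add(inner, x), self.ln_gain, self.ln_bias)


class EncoderBlock:
    """One BiGRU -> (MHA | identity) -> FFN unit; the stack repeats it N times."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator, name: str):
        self.config = config
        self.bigru = BiGRU(config.m, config.gru_hidden, rng, f"{name}.bigru")
        self.mha = (
            MultiHeadAttention(config, rng, f"{name}.mha") if config.use_mha else None
        )
        self.ffn = FeedForward(config, rng, f"{name}.ffn")

    def parameters(self) -> list[Parameter]:
        ps = self.bigru.parameters()
        if self.mha is not None:
            ps += self.mha.parameters()
        return ps + self.ffn.parameters()

    def __call__(
        self,
        x: Tensor,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray | None]:
        ctx = self.bigru(x, mask)
        attn = None
        if self.mha is not None:
            ctx, attn = self.mha(ctx, ctx, ctx, mask)
        out = self.ffn(ctx, training=training, rng=rng)
        return out, attn


class TaggerModel:
    """The full encoder from token ids to tag-space emission scores.

    The padding embedding row (index 0) is pinned to the zero vector: it is
    zeroed at initialization and its gradient is discarded by the optimizer,
    so a padded position contributes only its positional-encoding row before
    the recurrent stack (and nothing at all after CRF masking).
    """

    def __init__(
        self,
        config: ModelConfig,
        vocab_size: int,
        tagset_size: int,
        rng: np.random.Generator,
    ):
        if config.max_len is None:
            raise ValueError("ModelConfig.max_len must be set before building a model")
        self.config = config
        self.vocab_size = vocab_size
        self.tagset_size = tagset_size
        emb = rng.normal(0.0, 1.0 / np.sqrt(config.m), size=(vocab_size, config.m))
        emb[PAD_INDEX] = 0.0
        self.embedding = Parameter(emb, "embedding")
        self.pos_table = positional_encoding(config.max_len, config.m)
        self.blocks = [
            EncoderBlock(config, rng, f"encoder{i}") for i in range(config.n_encoders)
        ]
        self.h3 = Linear(config.m, tagset_size, rng, "h3")

    def parameters(self) -> list[Parameter]:
        ps = [self.embedding]
        for blk in self.blocks:
            ps += blk.parameters()
        return ps + self.h3.parameters()

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for p in self.parameters():
            yield p.name, p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def embed_and_position(self, batch: EncodedBatch) -> Tensor:
        """Embedding lookup plus the positional row, elementwise."""
        ids = batch.token_ids
        if ids.max() >= self.vocab_size or ids.min() < 0:
            raise ValueError(
                f"token id out of range [0, {self.vocab_size}): "
                f"[{ids.min()}, {ids.max()}]"
            )
        if batch.padded_length > self.pos_table.shape[0]:
            raise ValueError(
                f"batch padded to {batch.padded_length} exceeds positional "
                f"table length {self.pos_table.shape[0]}"
            )
        emb = ag.embedding(self.embedding, ids)
        return ag.add(emb, Tensor(self.pos_table[: batch.padded_length]))

    def emissions(
        self,
        batch: EncodedBatch,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_attention: bool = False,
    ):
        """Run the full encoder; returns the B x d x n_tags emission Tensor.

        With ``return_attention=True`` also returns the list of per-block
        attention-weight arrays (each B x h x d x d, or None without MHA).
        """
        x = self.embed_and_position(batch)
        attns: list[np.ndarray | None] = []
        for blk in self.blocks:
            x, attn = blk(x, batch.mask, training=training, rng=rng)
            attns.append(attn)
        scores = self.h3(x)
        if return_attention:
            return scores, attns
        return scores

    def emission_scores(self, batch: EncodedBatch) -> EmissionScores:
        """Evaluation-mode emissions as a plain-array container."""
        scores = self.emissions(batch, training=False)
        return EmissionScores(scores.data.copy(), batch.mask.copy())


def parameter_count(
    config: ModelConfig, vocab_size: int, tagset_size: int
) -> int:
    """Closed-form trainable-parameter total for a model configuration.

    Counts embedding, per-block BiGRU + (optional) attention + feed-forward
    parameters, the final tag projection, and the CRF transition scores
    (start/end vectors plus the pairwise matrix), matching exactly what a
    built model instantiates.
    """
    m, H, K = config.m, config.gru_hidden, tagset_size
    emb = vocab_size * m
    gru = 2 * (m * 3 * H + H * 3 * H + 3 * H)
    mha = (4 * (m * m + m) + 2 * m) if config.use_mha else 0
    ffn = (m * config.d_ff + config.d_ff) + (config.d_ff * m + m) + 2 * m
    h3 = m * K + K
    crf = K * K + 2 * K
    return emb + config.n_encoders * (gru + mha + ffn) + h3 + crf


def mha_parameter_delta(config: ModelConfig) -> int:
    """Parameters removed by the no-attention ablation (per stack)."""
    m = config.m
    return config.n_encoders * (4 * (m * m + m) + 2 * m)
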