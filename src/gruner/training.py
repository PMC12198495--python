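"""Supervised training (Adam on the masked CRF negative log-likelihood),
checkpointing, and Viterbi prediction.

The loop is deliberately plain: shuffle sentences each epoch, encode
mini-batches padded to the corpus-level maximum sentence length (so the
positional table is built once), run the encoder in training mode (dropout
on), and take an Adam step on the mean per-sentence CRF NLL.  A single seed
drives parameter initialization, shuffling, and dropout, so a run is
reproducible bit for bit on one platform.  There is no early stopping and
no development set — the defaults follow the two-epoch recipe with
learning rate 1e-3.
"""

from __future__ import annotations

import io
import json
import sys
import time
import zipfile
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Parameter
from .corpus import (
    Corpus,
    EncodedBatch,
    Sentence,
    TagScheme,
    Vocabulary,
    build_tag_scheme,
    build_vocabulary,
    encode_batch,
    PAD_INDEX,
)
from .crf import CRFLayer, viterbi_decode
from .model import ModelConfig, TaggerModel


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam moments at conventional defaults)."""

    learning_rate: float = 1e-3
    epochs: int = 2
    batch_size: int = 32
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported")


class Adam:
    """Adam with bias correction; lr=0 leaves parameters untouched."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


@dataclass
class Checkpoint:
    """Everything needed to reload a trained tagger and reproduce its output."""

    model: TaggerModel
    crf: CRFLayer
    model_config: ModelConfig
    train_config: TrainConfig
    vocab: Vocabulary
    scheme: TagScheme
    loss_trace: list[float] = field(default_factory=list)

    def n_parameters(self) -> int:
        return self.model.n_parameters() + sum(
            p.data.size for p in self.crf.parameters()
        )

    def save(self, path: str | Path) -> None:
        """Write a single-file archive: arrays + JSON metadata."""
        path = Path(path)
        arrays = {p.name: p.data for p in self.model.parameters()}
        arrays.update({p.name: p.data for p in self.crf.parameters()})
        meta = {
            "model_config": asdict(self.model_config),
            "train_config": asdict(self.train_config),
            "vocab": self.vocab.token_to_index,
            "classes": list(self.scheme.classes),
            "loss_trace": self.loss_trace,
            "format_version": 1,
        }
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("arrays.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        with zipfile.ZipFile(path, "r") as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            model_config = ModelConfig(**meta["model_config"])
            train_config = TrainConfig(**meta["train_config"])
            vocab = Vocabulary(meta["vocab"])
            scheme = build_tag_scheme(meta["classes"])
            rng = np.random.default_rng(0)  # placeholder init, overwritten below
            model = TaggerModel(model_config, len(vocab), len(scheme), rng)
            crf = CRFLayer(len(scheme), rng)
            for p in model.parameters() + crf.parameters():
                p.data = np.array(arrays[p.name], dtype=np.float64)
        return cls(
            model,
            crf,
            model_config,
            train_config,
            vocab,
            scheme,
            list(meta["loss_trace"]),
        )


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def train_model(
    train_corpus: Corpus,
    model_config: ModelConfig,
    train_config: TrainConfig,
    min_count: int = 1,
    verbose: bool = True,
) -> Checkpoint:
    """Fit the tagger on ``train_corpus`` and return a checkpoint.

    The padded length ``d`` defaults to the longest training sentence when
    ``model_config.max_len`` is unset.  The padding embedding row stays
    pinned at zero (its gradient is dropped before each Adam step).
    """
    if len(train_corpus) == 0:
        raise ValueError("cannot train on an empty corpus")
    if len(train_corpus.entity_classes) == 0:
        raise ValueError("training corpus declares no entity classes")
    vocab = build_vocabulary(train_corpus, min_count=min_count)
    scheme = build_tag_scheme(train_corpus.entity_classes)
    if model_config.max_len is None:
        model_config = model_config.with_max_len(train_corpus.max_sentence_length())
    rng = np.random.default_rng(train_config.seed)
    model = TaggerModel(model_config, len(vocab), len(scheme), rng)
    crf = CRFLayer(len(scheme), rng)
    params = model.parameters() + crf.parameters()
    opt = Adam(params, lr=train_config.learning_rate)
    sentences = list(train_corpus.sentences)
    loss_trace: list[float] = []
    for epoch in range(1, train_config.epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(len(sentences))
        epoch_losses: list[float] = []
        for lo in range(0, len(sentences), train_config.batch_size):
            batch_sents = [sentences[i] for i in order[lo : lo + train_config.batch_size]]
            batch = encode_batch(batch_sents, vocab, scheme, model_config.max_len)
            opt.zero_grad()
            emissions = model.emissions(batch, training=True, rng=rng)
            loss = crf.nll(emissions, batch.tag_ids, batch.mask)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss {loss.item()} at epoch {epoch}"
                )
            loss.backward()
            model.embedding.grad[PAD_INDEX] = 0.0  # keep the PAD row at zero
            opt.step()
            epoch_losses.append(loss.item())
        mean_loss = float(np.mean(epoch_losses))
        loss_trace.append(mean_loss)
        if verbose:
            _log(
                f"epoch={epoch} mean_loss={mean_loss:.6f} "
                f"wall={time.perf_counter() - t0:.2f}s"
            )
    return Checkpoint(model, crf, model_config, train_config, vocab, scheme, loss_trace)


def predict(
    checkpoint: Checkpoint,
    sentences: Sequence[Sentence] | Sequence[Sequence[str]],
    batch_size: int = 64,
    constrain_bio: bool = False,
) -> list[Sentence]:
    """Viterbi-decode tags for token sequences (dropout off).

    Accepts :class:`Sentence` objects (tags ignored) or bare token lists;
    returns tagged :class:`Sentence` objects in input order.
    """
    token_seqs: list[tuple[str, ...]] = [
        tuple(s.tokens) if isinstance(s, Sentence) else tuple(s) for s in sentences
    ]
    model, crf, scheme = checkpoint.model, checkpoint.crf, checkpoint.scheme
    trans = crf.transition_matrix()
    idx2tag = scheme.index_to_tag
    out: list[Sentence] = []
    for lo in range(0, len(token_seqs), batch_size):
        chunk = token_seqs[lo : lo + batch_size]
        batch = encode_batch(
            [Sentence(toks, ("O",) * len(toks)) for toks in chunk],
            checkpoint.vocab,
            None,
            checkpoint.model_config.max_len,
            with_tags=False,
        )
        scores = model.emissions(batch, training=False).data
        for b, toks in enumerate(chunk):
            path = viterbi_decode(
                scores[b],
                trans,
                batch.mask[b],
                constrain_bio=constrain_bio,
                n_classes=len(scheme.classes),
            )
            out.append(Sentence(toks, tuple(idx2tag[int(i)] for i in path)))
    return out


def predict_corpus(
    checkpoint: Checkpoint, corpus: Corpus, constrain_bio: bool = False
) -> Corpus:
    """Tag every sentence of ``corpus``, keeping its class inventory."""
    tagged = predict(checkpoint, corpus.sentences, constrain_bio=constrain_bio)
    return Corpus(tuple(tagged), checkpoint.scheme.classes)
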