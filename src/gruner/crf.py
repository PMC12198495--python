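"""Masked linear-chain CRF: scoring, exact log-partition, NLL, and Viterbi.

A tag path ``y = (y_1 .. y_L)`` over the ``L`` real (unmasked) positions of
a sentence is scored as

    score(y) = start[y_1] + sum_t emissions[t, y_t]
             + sum_t trans[y_t, y_{t+1}] + end[y_L]

The conditional probability of a path is ``exp(score(y) - logZ)`` where the
log-partition ``logZ`` sums ``exp(score)`` over all ``K^L`` paths; it is
computed exactly by the forward recursion in log space.  Training minimizes
the negative log-likelihood ``logZ - score(gold)``; decoding maximizes the
path score with the Viterbi dynamic program.  Masked (padded) positions
contribute nothing anywhere.

Two parallel surfaces are provided:

* plain-NumPy, single-sentence functions (:func:`sequence_score`,
  :func:`log_partition`, :func:`crf_nll`, :func:`viterbi_decode`,
  :func:`enumerate_decode`) used at decode/evaluation time and as the
  specification of the semantics — :func:`enumerate_decode` and the
  exhaustive sum are deliberately brute-force test oracles;
* a differentiable batched layer (:class:`CRFLayer`) with learnable
  transition scores used inside the training loss.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from . import autograd as ag
from .autograd import Parameter, Tensor

_BIO_FORBIDDEN = -1e4  # decode-time penalty when BIO transition constraints are on


@dataclass
class TransitionMatrix:
    """Learned tag-to-tag transition scores with start/end boundary vectors.

    ``trans[i, j]`` scores tag ``i`` followed by tag ``j``.
    """

    start: NDArray[np.float64]
    trans: NDArray[np.float64]
    end: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.float64)
        self.trans = np.asarray(self.trans, dtype=np.float64)
        self.end = np.asarray(self.end, dtype=np.float64)
        K = self.start.shape[0]
        if self.trans.shape != (K, K) or self.end.shape != (K,):
            raise ValueError("inconsistent transition shapes")
        if not (
            np.all(np.isfinite(self.start))
            and np.all(np.isfinite(self.trans))
            and np.all(np.isfinite(self.end))
        ):
            raise ValueError("transition scores must be finite")

    @property
    def n_tags(self) -> int:
        return self.start.shape[0]


def _unmasked(emissions: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Emission rows at real positions, in order."""
    emissions = np.asarray(emissions, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if mask.shape[0] != emissions.shape[0]:
        raise ValueError("mask length must match emission length")
    if not mask.any():
        raise ValueError("mask selects no positions")
    return emissions[mask]


def sequence_score(
    emissions: np.ndarray,
    trans: TransitionMatrix,
    path: np.ndarray,
    mask: np.ndarray,
) -> float:
    """Unnormalized score of ``path`` over the unmasked positions."""
    em = _unmasked(emissions, mask)
    path = np.asarray(path, dtype=np.int64)
    L = em.shape[0]
    if path.shape[0] != L:
        raise ValueError(f"path length {path.shape[0]} != unmasked length {L}")
    score = trans.start[path[0]] + trans.end[path[-1]]
    score += em[np.arange(L), path].sum()
    if L > 1:
        score += trans.trans[path[:-1], path[1:]].sum()
    return float(score)


def log_partition(
    emissions: np.ndarray, trans: TransitionMatrix, mask: np.ndarray
) -> float:
    """log sum over all tag paths of exp(sequence_score), via the forward pass."""
    em = _unmasked(emissions, mask)
    alpha = trans.start + em[0]
    for t in range(1, em.shape[0]):
        # alpha[j] <- logsumexp_i(alpha[i] + trans[i, j]) + em[t, j]
        scores = alpha[:, None] + trans.trans
        amax = scores.max(axis=0)
        alpha = amax + np.log(np.exp(scores - amax).sum(axis=0)) + em[t]
    alpha = alpha + trans.end
    amax = alpha.max()
    return float(amax + np.log(np.exp(alpha - amax).sum()))


def crf_nll(
    emissions: np.ndarray,
    trans: TransitionMatrix,
    gold: np.ndarray,
    mask: np.ndarray,
) -> float:
    """Negative log-likelihood of the gold path; always >= 0."""
    return log_partition(emissions, trans, mask) - sequence_score(
        emissions, trans, gold, mask
    )


def viterbi_decode(
    emissions: np.ndarray,
    trans: TransitionMatrix,
    mask: np.ndarray,
    constrain_bio: bool = False,
    n_classes: int | None = None,
) -> np.ndarray:
    """Highest-scoring tag path over the unmasked positions.

    Ties are broken toward the lowest tag index at every argmax.  With
    ``constrain_bio=True``, transitions into ``I-c`` from anything other
    than ``B-c``/``I-c`` (including the start boundary) are penalized by a
    large constant, assuming the tag layout O=0 then (B-c, I-c) pairs.
    """
    em = _unmasked(emissions, mask)
    T = trans
    if constrain_bio:
        if n_classes is None:
            n_classes = (trans.n_tags - 1) // 2
        T = TransitionMatrix(
            trans.start + _bio_start_penalty(trans.n_tags, n_classes),
            trans.trans + _bio_transition_penalty(trans.n_tags, n_classes),
            trans.end.copy(),
        )
    L, K = em.shape
    delta = T.start + em[0]
    back = np.zeros((L, K), dtype=np.int64)
    for t in range(1, L):
        scores = delta[:, None] + T.trans  # K_prev x K_next
        back[t] = scores.argmax(axis=0)  # argmax -> first (lowest) index on ties
        delta = scores[back[t], np.arange(K)] + em[t]
    delta = delta + T.end
    path = np.zeros(L, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _bio_start_penalty(n_tags: int, n_classes: int) -> np.ndarray:
    pen = np.zeros(n_tags)
    for c in range(n_classes):
        pen[2 + 2 * c] = _BIO_FORBIDDEN  # start -> I-c
    return pen


def _bio_transition_penalty(n_tags: int, n_classes: int) -> np.ndarray:
    pen = np.zeros((n_tags, n_tags))
    for c in range(n_classes):
        i_tag = 2 + 2 * c
        b_tag = 1 + 2 * c
        pen[:, i_tag] = _BIO_FORBIDDEN
        pen[b_tag, i_tag] = 0.0
        pen[i_tag, i_tag] = 0.0
    return pen


def enumerate_decode(
    emissions: np.ndarray, trans: TransitionMatrix, mask: np.ndarray
) -> np.ndarray:
    """Brute-force argmax over all ``K^L`` paths (test oracle).

    Iterates paths in lexicographic order and keeps the first strictly best
    one, i.e. the lexicographically smallest optimum.  Refuses instances
    with more than 10^6 paths.
    """
    em = _unmasked(emissions, mask)
    L, K = em.shape
    if K**L > 10**6:
        raise ValueError(f"{K}^{L} paths exceed the enumeration limit")
    best_path: tuple[int, ...] | None = None
    best_score = -np.inf
    for path in itertools.product(range(K), repeat=L):
        s = sequence_score(em, trans, np.array(path), np.ones(L, dtype=np.int64))
        if s > best_score:
            best_score = s
            best_path = path
    assert best_path is not None
    return np.array(best_path, dtype=np.int64)


class CRFLayer:
    """Learnable transitions plus the differentiable batched NLL."""

    def __init__(self, n_tags: int, rng: np.random.Generator):
        self.n_tags = n_tags
        scale = 0.1
        self.start = Parameter(rng.normal(0.0, scale, size=n_tags), "crf.start")
        self.trans = Parameter(rng.normal(0.0, scale, size=(n_tags, n_tags)), "crf.trans")
        self.end = Parameter(rng.normal(0.0, scale, size=n_tags), "crf.end")

    def parameters(self) -> list[Parameter]:
        return [self.start, self.trans, self.end]

    def transition_matrix(self) -> TransitionMatrix:
        return TransitionMatrix(
            self.start.data.copy(), self.trans.data.copy(), self.end.data.copy()
        )

    def nll(self, emissions: Tensor, tag_ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean per-sentence negative log-likelihood over the batch.

        ``emissions`` is B x T x K; ``tag_ids``/``mask`` are B x T integer
        arrays.  Positions with ``mask == 0`` contribute nothing: their
        emission terms are multiplied out, transitions across them never
        occur (padding is a contiguous tail), and the forward recursion
        carries its state unchanged through them.
        """
        B, T, K = emissions.shape
        tag_ids = np.asarray(tag_ids, dtype=np.int64)
        maskf = np.asarray(mask, dtype=np.float64)
        lengths = maskf.sum(axis=1).astype(np.int64)
        if np.any(lengths < 1):
            raise ValueError("every sentence in the batch needs >= 1 real position")
        bidx = np.arange(B)

        # gold path score
        em_gold = emissions[bidx[:, None], np.arange(T)[None, :], tag_ids]  # B x T
        gold = ag.tsum(ag.mul(em_gold, Tensor(maskf)))
        gold = ag.add(gold, ag.tsum(self.start[tag_ids[:, 0]]))
        gold = ag.add(gold, ag.tsum(self.end[tag_ids[bidx, lengths - 1]]))
        if T > 1:
            pair = self.trans[tag_ids[:, :-1], tag_ids[:, 1:]]  # B x (T-1)
            gold = ag.add(gold, ag.tsum(ag.mul(pair, Tensor(maskf[:, 1:]))))

        # log-partition by the forward recursion
        alpha = ag.add(ag.reshape(self.start, (1, K)), emissions[:, 0, :])
        for t in range(1, T):
            m_t = maskf[:, t : t + 1]
            if not m_t.any():
                break
            scores = ag.add(
                ag.add(
                    ag.reshape(alpha, (B, K, 1)),
                    ag.reshape(self.trans, (1, K, K)),
                ),
                ag.reshape(emissions[:, t, :], (B, 1, K)),
            )
            new = ag.logsumexp(scores, axis=1)
            alpha = ag.add(
                ag.mul(new, Tensor(m_t)), ag.mul(alpha, Tensor(1.0 - m_t))
            )
        logZ = ag.tsum(ag.logsumexp(ag.add(alpha, ag.reshape(self.end, (1, K))), axis=1))

        return ag.mul(ag.sub(logZ, gold), 1.0 / B)
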