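"""Reading, writing, and indexing of CoNLL-style BIO-tagged corpora.

The on-disk dialect is the two-column layout used by the standard biomedical
NER benchmark distributions (NCBI Disease, BC5CDR, BC4CHEMD, BC2GM, JNLPBA,
LINNAEUS, Species-800): one ``<token><TAB><tag>`` line per token, one blank
line between sentences, UTF-8 throughout.  Tags follow the BIO scheme:
``O`` for tokens outside any entity, ``B-<class>`` for the first token of an
entity of a given class, ``I-<class>`` for its continuation.

This module also builds the two index spaces the network consumes: a
:class:`Vocabulary` mapping tokens to integer ids (with reserved padding and
unknown-token ids) and a :class:`TagScheme` mapping the ``2M + 1`` tags of an
``M``-class corpus to contiguous ids, plus the padded/masked integer batches
(:class:`EncodedBatch`) that bridge text and the model.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
OUTSIDE_TAG = "O"

_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the two-column BIO layout."""


class SentenceTooLongError(ValueError):
    """Raised when a sentence exceeds the model's padded length ``d``."""


@dataclass(frozen=True)
class Sentence:
    """A tokenized sentence with one BIO tag per token."""

    tokens: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"token/tag length mismatch: {len(self.tokens)} != {len(self.tags)}"
            )
        if len(self.tokens) == 0:
            raise ValueError("a sentence must contain at least one token")
        for tag in self.tags:
            if not _TAG_RE.match(tag):
                raise ValueError(f"invalid BIO tag {tag!r}")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of sentences plus its entity-class inventory."""

    sentences: tuple[Sentence, ...]
    entity_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sentences", tuple(self.sentences))
        object.__setattr__(self, "entity_classes", tuple(self.entity_classes))
        known = set(self.entity_classes)
        for sent in self.sentences:
            for tag in sent.tags:
                if tag != OUTSIDE_TAG and tag[2:] not in known:
                    raise ValueError(
                        f"tag {tag!r} uses a class not in entity_classes {known}"
                    )

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def n_classes(self) -> int:
        return len(self.entity_classes)

    def max_sentence_length(self) -> int:
        return max(len(s) for s in self.sentences)


@dataclass(frozen=True)
class Vocabulary:
    """Bijection token <-> contiguous index with reserved PAD=0, UNK=1."""

    token_to_index: dict[str, int]

    def __post_init__(self) -> None:
        t2i = dict(self.token_to_index)
        if t2i.get(PAD_TOKEN) != PAD_INDEX or t2i.get(UNK_TOKEN) != UNK_INDEX:
            raise ValueError("vocabulary must reserve PAD at 0 and UNK at 1")
        if sorted(t2i.values()) != list(range(len(t2i))):
            raise ValueError("vocabulary indices must be contiguous from 0")
        object.__setattr__(self, "token_to_index", t2i)

    def __len__(self) -> int:
        return len(self.token_to_index)

    def lookup(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    @property
    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}


@dataclass(frozen=True)
class TagScheme:
    """Bijection tag <-> index: O at 0, then (B-c, I-c) per class in order."""

    classes: tuple[str, ...]
    tag_to_index: dict[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        classes = tuple(self.classes)
        if len(classes) == 0:
            raise ValueError("a tag scheme needs at least one entity class")
        if len(set(classes)) != len(classes):
            raise ValueError(f"duplicate class names in {classes}")
        t2i = {OUTSIDE_TAG: 0}
        for c in classes:
            t2i[f"B-{c}"] = len(t2i)
            t2i[f"I-{c}"] = len(t2i)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "tag_to_index", t2i)

    def __len__(self) -> int:
        return len(self.tag_to_index)

    def encode(self, tag: str) -> int:
        try:
            return self.tag_to_index[tag]
        except KeyError:
            raise KeyError(f"tag {tag!r} not in scheme over classes {self.classes}")

    def decode(self, index: int) -> str:
        return self.index_to_tag[index]

    @property
    def index_to_tag(self) -> dict[int, str]:
        return {i: t for t, i in self.tag_to_index.items()}


@dataclass(frozen=True)
class EncodedBatch:
    """Padded index matrices plus the binary mask consumed by the network.

    ``token_ids`` and ``tag_ids`` are ``B x d`` integer arrays right-padded
    with PAD (0); ``mask[b, t] == 1`` iff position ``t`` is a real token of
    sentence ``b``.  ``tag_ids`` is all-PAD when the batch was encoded
    without gold tags (prediction time).
    """

    token_ids: np.ndarray
    tag_ids: np.ndarray
    mask: np.ndarray
    lengths: np.ndarray

    @property
    def batch_size(self) -> int:
        return int(self.token_ids.shape[0])

    @property
    def padded_length(self) -> int:
        return int(self.token_ids.shape[1])


def read_bio_corpus(path: str | Path, column_separator: str = "\t") -> Corpus:
    """Parse a two-column BIO file into a :class:`Corpus`.

    Blank lines terminate sentences; trailing blank lines are tolerated.
    Raises :class:`CorpusFormatError` (naming the offending line) for rows
    with fewer than two columns or tags outside the BIO grammar, and
    ``FileNotFoundError`` for a missing file.
    """
    path = Path(path)
    sentences: list[Sentence] = []
    tokens: list[str] = []
    tags: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.strip() == "":
                if tokens:
                    sentences.append(Sentence(tuple(tokens), tuple(tags)))
                    tokens, tags = [], []
                continue
            cols = line.split(column_separator)
            if len(cols) < 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected >=2 columns separated by "
                    f"{column_separator!r}, got {line!r}"
                )
            token, tag = cols[0], cols[-1]
            if not _TAG_RE.match(tag):
                raise CorpusFormatError(
                    f"{path}:{lineno}: tag {tag!r} does not match the BIO grammar"
                )
            tokens.append(token)
            tags.append(tag)
    if tokens:
        sentences.append(Sentence(tuple(tokens), tuple(tags)))
    if not sentences:
        raise CorpusFormatError(f"{path}: no sentences found")
    return Corpus(tuple(sentences), infer_classes(sentences))


def infer_classes(sentences: Iterable[Sentence]) -> tuple[str, ...]:
    """Entity classes in order of first appearance across the sentences."""
    seen: dict[str, None] = {}
    for sent in sentences:
        for tag in sent.tags:
            if tag != OUTSIDE_TAG:
                seen.setdefault(tag[2:], None)
    return tuple(seen)


def write_bio_corpus(
    corpus: Corpus, path: str | Path, column_separator: str = "\t"
) -> None:
    """Write ``corpus`` in the two-column dialect (blank line per sentence)."""
    if len(corpus) == 0:
        raise ValueError("refusing to write an empty corpus")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for sent in corpus.sentences:
            for token, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{token}{column_separator}{tag}\n")
            fh.write("\n")


def build_vocabulary(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Index tokens with frequency >= ``min_count``.

    Ordering is deterministic: descending frequency, ties broken
    lexicographically.  Tokens below the threshold fall back to UNK at
    lookup time.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(tok for sent in corpus.sentences for tok in sent.tokens)
    kept = sorted(
        (tok for tok, n in counts.items() if n >= min_count),
        key=lambda tok: (-counts[tok], tok),
    )
    t2i = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    for tok in kept:
        t2i[tok] = len(t2i)
    return Vocabulary(t2i)


def build_tag_scheme(classes: Sequence[str]) -> TagScheme:
    """Tag scheme of size ``2M + 1``: a single shared O plus B-c/I-c per class."""
    return TagScheme(tuple(classes))


def encode_batch(
    sentences: Sequence[Sentence],
    vocab: Vocabulary,
    scheme: TagScheme | None,
    max_len: int,
    with_tags: bool = True,
) -> EncodedBatch:
    """Right-pad sentences to ``max_len`` and map tokens/tags to indices.

    A sentence longer than ``max_len`` raises :class:`SentenceTooLongError`
    rather than being truncated, since ``max_len`` is meant to be the
    longest training sentence.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if not sentences:
        raise ValueError("cannot encode an empty list of sentences")
    B = len(sentences)
    token_ids = np.zeros((B, max_len), dtype=np.int64)
    tag_ids = np.zeros((B, max_len), dtype=np.int64)
    mask = np.zeros((B, max_len), dtype=np.int64)
    lengths = np.zeros(B, dtype=np.int64)
    for b, sent in enumerate(sentences):
        n = len(sent)
        if n > max_len:
            raise SentenceTooLongError(
                f"sentence {b} has {n} tokens, exceeding max_len={max_len}: "
                f"{' '.join(sent.tokens[:8])}..."
            )
        lengths[b] = n
        token_ids[b, :n] = [vocab.lookup(tok) for tok in sent.tokens]
        mask[b, :n] = 1
        if with_tags:
            if scheme is None:
                raise ValueError("with_tags=True requires a tag scheme")
            tag_ids[b, :n] = [scheme.encode(tag) for tag in sent.tags]
    return EncodedBatch(token_ids, tag_ids, mask, lengths)
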