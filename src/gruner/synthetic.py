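"""Reproducible synthetic BIO corpora for exercising the tagger end to end.

Real biomedical NER corpora pair sentences with contiguous entity mentions
(genes, diseases, chemicals, species) marked as ``B-c I-c ...`` runs.  The
generator emulates exactly that structure over a closed vocabulary: each
entity class draws its mention tokens from a private lexicon disjoint from
the background vocabulary (and from every other class's lexicon), so the
token -> class mapping is learnable by a small model and an overfitting run
is a meaningful end-to-end check.  It does not attempt to mimic real PubMed
token frequencies or the class imbalance of the benchmark sets.

Sentences are built position by position: at each free position an entity
starts with probability ``entity_rate``, its length drawn uniformly from
``entity_length_range`` (clipped at the sentence end); otherwise a
background token tagged ``O`` is emitted.  All randomness flows from the
single seed in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .corpus import Corpus, Sentence


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus and their realism constraints.

    Defaults describe a small two-class corpus (gene and disease mentions)
    with entity density comparable to the denser benchmark corpora: an
    entity starts at roughly one in six free positions and spans 1-3
    tokens.
    """

    n_sentences: int = 100
    sentence_length_range: tuple[int, int] = (5, 12)
    vocab_size: int = 120
    classes: tuple[str, ...] = ("Gene", "Disease")
    entity_rate: float = 0.15
    entity_length_range: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_sentences < 1:
            problems.append("n_sentences must be >= 1")
        lo, hi = self.sentence_length_range
        if not (1 <= lo <= hi):
            problems.append("sentence_length_range must satisfy 1 <= min <= max")
        elo, ehi = self.entity_length_range
        if not (1 <= elo <= ehi):
            problems.append("entity_length_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.entity_rate <= 1.0):
            problems.append("entity_rate must be in [0, 1]")
        if len(self.classes) != len(set(self.classes)):
            problems.append("class names must be unique")
        if self.vocab_size < max(1, len(self.classes)) * ehi:
            problems.append(
                "vocab_size must be >= n_classes * max entity length so each "
                "class can have a lexicon"
            )
        if problems:
            raise ValueError("invalid GeneratorConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sentence_length_range"] = list(self.sentence_length_range)
        d["entity_length_range"] = list(self.entity_length_range)
        d["classes"] = list(self.classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("sentence_length_range", "entity_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        return cls(**d)


def _lexicons(config: GeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Split the closed vocabulary into background tokens and per-class lexicons.

    Each class receives an equal share of (at most) half the vocabulary,
    but never fewer tokens than the longest possible entity; the rest is
    background.  Token strings are synthetic ("w0007", "Gene_003", ...).
    """
    n_classes = len(config.classes)
    if n_classes == 0:
        return [f"w{i:04d}" for i in range(config.vocab_size)], {}
    per_class = max(
        config.entity_length_range[1], config.vocab_size // (2 * n_classes)
    )
    n_background = config.vocab_size - per_class * n_classes
    if n_background < 1:
        per_class = config.entity_length_range[1]
        n_background = config.vocab_size - per_class * n_classes
    background = [f"w{i:04d}" for i in range(max(n_background, 0))]
    lexicons = {
        c: [f"{c}_{j:03d}" for j in range(per_class)] for c in config.classes
    }
    return background, lexicons


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Draw a corpus fully determined by ``config`` (including its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    background, lexicons = _lexicons(config)
    classes = tuple(config.classes)
    lo, hi = config.sentence_length_range
    elo, ehi = config.entity_length_range
    sentences: list[Sentence] = []
    for _ in range(config.n_sentences):
        n = int(rng.integers(lo, hi + 1))
        tokens: list[str] = []
        tags: list[str] = []
        pos = 0
        while pos < n:
            if classes and (not background or rng.random() < config.entity_rate):
                c = classes[int(rng.integers(0, len(classes)))]
                length = min(int(rng.integers(elo, ehi + 1)), n - pos)
                lex = lexicons[c]
                for j in range(length):
                    tokens.append(lex[int(rng.integers(0, len(lex)))])
                    tags.append(("B-" if j == 0 else "I-") + c)
                pos += length
            else:
                tokens.append(background[int(rng.integers(0, len(background)))])
                tags.append("O")
                pos += 1
        sentences.append(Sentence(tuple(tokens), tuple(tags)))
    return Corpus(tuple(sentences), classes)


def split_corpus(
    corpus: Corpus, fractions: tuple[float, float], seed: int
) -> tuple[Corpus, Corpus]:
    """Deterministic disjoint train/test partition of the sentences."""
    train_frac, test_frac = fractions
    if train_frac <= 0 or test_frac <= 0:
        raise ValueError("both fractions must be positive")
    if abs(train_frac + test_frac - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(corpus)
    n_train = int(round(train_frac * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(
            f"split of {n} sentences at {train_frac:.2f}/{test_frac:.2f} "
            "leaves an empty part"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    train = Corpus(
        tuple(corpus.sentences[i] for i in train_idx), corpus.entity_classes
    )
    test = Corpus(
        tuple(corpus.sentences[i] for i in test_idx), corpus.entity_classes
    )
    return train, test
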