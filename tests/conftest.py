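"""Shared fixtures: small corpora and one session-scoped overfitting run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from gruner.corpus import Corpus, Sentence
from gruner.model import ModelConfig
from gruner.synthetic import GeneratorConfig, generate_corpus
from gruner.training import TrainConfig, train_model

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

# Study conditions for the end-to-end learnability check: the generator's
# default two-class corpus (disjoint per-class lexicons), a narrow model,
# and the standard optimizer recipe (Adam, lr 1e-3, dropout 0.2).
OVERFIT_GENERATOR = GeneratorConfig(seed=11)
OVERFIT_MODEL = ModelConfig(m=32, h=4, d_ff=64)
OVERFIT_TRAIN = TrainConfig(learning_rate=1e-3, epochs=200, batch_size=16, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_corpus() -> Corpus:
    return Corpus(
        (
            Sentence(("IL-2", "binds", "NF-kB"), ("B-Gene", "O", "B-Gene")),
            Sentence(
                ("severe", "lung", "cancer", "observed"),
                ("O", "B-Disease", "I-Disease", "O"),
            ),
            Sentence(("nothing", "here"), ("O", "O")),
        ),
        ("Gene", "Disease"),
    )


@pytest.fixture(scope="session")
def overfit_run():
    """Train once on the default synthetic corpus; reused by several tests."""
    corpus = generate_corpus(OVERFIT_GENERATOR)
    checkpoint = train_model(corpus, OVERFIT_MODEL, OVERFIT_TRAIN, verbose=False)
    return corpus, checkpoint
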