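"""Shared fixtures: handwritten toy models and small synthetic corpora."""

import numpy as np
import pytest

from streetlex import embed, synthetic
from streetlex.embed import EmbeddingModel, Vocabulary


def make_model(vectors: dict) -> EmbeddingModel:
    """Build an EmbeddingModel from a {token: vector} dict (handwritten)."""
    tokens = list(vectors)
    mat = np.array([vectors[t] for t in tokens], dtype=np.float32)
    vocab = Vocabulary({t: i for i, t in enumerate(tokens)}, tokens,
                       np.ones(len(tokens)), 1)
    return EmbeddingModel(vocab, mat, mat.shape[1], 5)


@pytest.fixture
def toy_model():
    """5-term, 3-d model with unambiguous handwritten geometry."""
    return make_model({
        "ganja": [1.0, 0.0, 0.0],
        "weed": [0.9, 0.1, 0.0],
        "kush": [0.7, 0.7, 0.0],
        "rain": [0.0, 1.0, 0.0],
        "sun": [-1.0, 0.2, 0.1],
    })


@pytest.fixture(scope="session")
def small_synthetic():
    """Seed-7 fixture corpus: 1000 docs from the standard study conditions."""
    cfg = synthetic.default_config(n_docs=1000, seed=7)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def medium_synthetic():
    """Seed-11 mid-size corpus (~200k tokens) for training-quality checks."""
    cfg = synthetic.default_config(n_docs=20_000, seed=11)
    return synthetic.generate(cfg)


@pytest.fixture(scope="session")
def medium_model(medium_synthetic):
    """CBOW model trained on the mid-size corpus (phrase-merged)."""
    from streetlex import phrases

    corpus, truth = medium_synthetic
    pm = phrases.build_phrase_model(corpus)
    merged = phrases.merge_phrases(corpus, pm)
    cfg = embed.TrainingConfig(dim=50, min_count=10, epochs=5, seed=11)
    return embed.train_cbow(merged, cfg), truth
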