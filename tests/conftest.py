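import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deepmethyl import (
    GloveConfig,
    KmerVocabulary,
    SyntheticSpec,
    build_cooccurrence,
    build_vocab,
    fit_glove,
    generate,
    tokenize_corpus,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_dataset():
    """60+60 labeled 41-bp fragments with a fully planted motif."""
    return generate(SyntheticSpec(n_pos=60, n_neg=60, seed=7))


@pytest.fixture(scope="session")
def tiny_embedding(tiny_dataset):
    """A small fitted GloVe embedding over the tiny corpus (d=8)."""
    vocab = build_vocab(tiny_dataset, 3)
    corpus = tokenize_corpus(tiny_dataset, vocab)
    X = build_cooccurrence(corpus, window=1)
    return fit_glove(X, GloveConfig(d=8, epochs=10, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
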