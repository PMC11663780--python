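import numpy as np
import pytest

from cognote.baselines import AttentionNetConfig, train_attention_net, train_boosted_trees
from cognote.corpus import Corpus, NoteSection, load_default_lexicon
from cognote.synthetic import load_default_phrase_bank, make_separable_corpus


@pytest.fixture(scope="session")
def lexicon():
    return load_default_lexicon()


@pytest.fixture(scope="session")
def bank():
    return load_default_phrase_bank()


@pytest.fixture(scope="session")
def separable():
    """Fixture corpus where 'dementia' alone separates the classes."""
    return make_separable_corpus(n=500, seed=11)


@pytest.fixture(scope="session")
def trees_model(separable):
    return train_boosted_trees(separable, seed=7)


@pytest.fixture(scope="session")
def net_model(separable):
    return train_attention_net(separable, AttentionNetConfig(epochs=10), seed=7)


def tiny_corpus(labels, texts=None, patients=None, name="tiny"):
    """Hand-rolled corpus helper for alignment/metric tests."""
    n = len(labels)
    texts = texts or [f"section text {i}" for i in range(n)]
    patients = patients or [f"p{i}" for i in range(n)]
    return Corpus(
        name,
        [
            NoteSection(f"s{i}", patients[i], texts[i], labels[i])
            for i in range(n)
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
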