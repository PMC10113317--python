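import numpy as np
import pytest

import opreport as op
from opreport.model import ModelConfig, init_model
from opreport.synthetic_corpus import SyntheticCorpusConfig


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticCorpusConfig:
    """A miniature corpus configuration for fast unit tests."""
    return SyntheticCorpusConfig(
        n_reports=6,
        sentences_per_report_range=(4, 10),
        target_total_sentences=40,
        n_keywords=20,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_corpus(tiny_config):
    grammar = op.generate_grammar(tiny_config)
    return op.generate_corpus(tiny_config, grammar)


@pytest.fixture(scope="session")
def tiny_grammar(tiny_config):
    return op.generate_grammar(tiny_config)


@pytest.fixture(scope="session")
def tiny_vocab(tiny_corpus):
    sentences = [s.text for s in tiny_corpus.all_sentences()]
    return op.train_tokenizer(sentences, op.TokenizerConfig(vocab_size=120))


@pytest.fixture(scope="session")
def tiny_model(tiny_vocab):
    cfg = ModelConfig(vocab_size=tiny_vocab.size, embedding_size=16,
                      hidden_size=12, max_decode_length=40, seed=7)
    return init_model(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
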