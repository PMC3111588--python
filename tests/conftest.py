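import pytest

from mmbdeid.corpus_io import Corpus, Message
from mmbdeid.lexicon import load_lexicons
from mmbdeid.pipeline import train_deidentifier
from mmbdeid.synthetic_data import GeneratorConfig, generate_corpus, split_corpus
from mmbdeid.tagger import TaggerConfig


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons()


@pytest.fixture()
def tiny_corpus():
    """Three messages, two boards, two threads, two authors."""
    return Corpus(
        [
            Message("m1", "b1", "t1", "kaygirl99", "Hi Lisa, how are you?\n\nKay"),
            Message("m2", "b1", "t1", "lisa22", "kay thanks so much!\nLisa"),
            Message("m3", "b2", "t2", "kaygirl99", "new board post with no names"),
        ]
    )


@pytest.fixture(scope="session")
def small_run():
    """A quick end-to-end train/test split for pipeline-level tests."""
    cfg = GeneratorConfig(
        n_boards=3, n_threads_per_board=4, n_messages_per_thread=8, seed=11
    )
    corpus, gold = generate_corpus(cfg)
    train_c, train_g, test_c, test_g = split_corpus(corpus, gold, 2 / 3, seed=11)
    deid = train_deidentifier(train_c, train_g, TaggerConfig(max_iter=60))
    return {
        "train_corpus": train_c,
        "train_gold": train_g,
        "test_corpus": test_c,
        "test_gold": test_g,
        "deid": deid,
    }


@pytest.fixture(scope="session")
def full_run():
    """The package's reference study conditions: the generator's default
    1000-message corpus, split 4 boards train / 1 board test, CRF trained
    at the default configuration."""
    corpus, gold = generate_corpus(GeneratorConfig(seed=1))
    train_c, train_g, test_c, test_g = split_corpus(corpus, gold, 0.8, seed=1)
    deid = train_deidentifier(train_c, train_g, TaggerConfig())
    return {
        "corpus": corpus,
        "gold": gold,
        "train_corpus": train_c,
        "train_gold": train_g,
        "test_corpus": test_c,
        "test_gold": test_g,
        "deid": deid,
    }
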