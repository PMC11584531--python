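import pytest

from pharmakeyword.ingest import Post
from pharmakeyword.lexicon import default_lexicon
from pharmakeyword.synthetic import SyntheticConfig
from pharmakeyword.textproc import TokenizedText, build_corpus


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture
def tiny_posts():
    """Three posts: one study-drug mention, one CGRP mention, one control."""
    return [
        Post.create("p1", 100, "Topamax question", "Side effects?"),
        Post.create("p2", 200, "", "started aimovig last week"),
        Post.create("p3", 300, "magnesium", "works for me"),
    ]


@pytest.fixture(scope="session")
def small_config():
    """A fast synthetic collection with two drugs and one planted signal."""
    return SyntheticConfig(
        n_posts=400,
        vocab_size=300,
        post_length_mean=30.0,
        drug_prevalence={"topiramate": 0.12, "erenumab": 0.06},
        planted_signals=(("topiramate", "appetite", 25.0),),
        seed=11,
    )


def corpus_of(label, *token_lists, prefix="x"):
    texts = [
        TokenizedText(f"{prefix}{i}", toks) for i, toks in enumerate(token_lists)
    ]
    return build_corpus(label, texts)
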