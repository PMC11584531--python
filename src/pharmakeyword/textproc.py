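"""Tokenization and corpus count tables.

The analysis operates on bags of surface-form words. Tokens are maximal
runs of ASCII letters; digits, punctuation and other symbols act as
separators (so ``"50mg"`` yields ``"mg"``, which is then dropped by the
length filter, rather than a fused pseudo-word). Tokens shorter than
``min_token_len`` letters are discarded. No stemming, stop-word removal
or spelling correction is applied: the pipeline works on raw surface
forms, so e.g. "taste" and "tastes" are distinct words.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["tokenize", "letter_runs", "alnum_runs", "TokenizedText", "Corpus", "build_corpus"]

_LETTER_RUN = re.compile(r"[a-z]+")
_ALNUM_RUN = re.compile(r"[a-z0-9]+")

#: Minimum token length kept by :func:`tokenize`. Words with fewer than
#: 3 characters are removed; length-3 words are kept.
DEFAULT_MIN_TOKEN_LEN = 3


def letter_runs(text: str) -> list[str]:
    """Maximal runs of letters in ``text`` (lowercased), no length filter."""
    return _LETTER_RUN.findall(text.lower())


def alnum_runs(text: str) -> list[str]:
    """Maximal runs of letters-or-digits in ``text`` (lowercased).

    The token-boundary primitive for drug-name matching: a fused dose
    like ``"topamax50"`` stays a single token and therefore does not
    match the bare synonym, while ``"topamax!"`` or ``"topamax."``
    still does.
    """
    return _ALNUM_RUN.findall(text.lower())


def tokenize(text: str, min_token_len: int = DEFAULT_MIN_TOKEN_LEN) -> list[str]:
    """Split normalized text into analysis tokens.

    Splits on maximal runs of non-letter characters and keeps only
    pure-letter units of at least ``min_token_len`` characters,
    preserving order and multiplicity.

    >>> tokenize("topamax 50mg made me so foggy!!")
    ['topamax', 'made', 'foggy']
    """
    return [t for t in letter_runs(text) if len(t) >= min_token_len]


@dataclass(frozen=True)
class TokenizedText:
    """One post's filtered token sequence."""

    post_id: str
    tokens: tuple[str, ...]

    def __init__(self, post_id: str, tokens: Iterable[str]):
        object.__setattr__(self, "post_id", post_id)
        object.__setattr__(self, "tokens", tuple(tokens))

    @property
    def length(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """A labeled collection of tokenized texts with aggregate counts.

    ``total_tokens`` is the corpus word total (the n of the token-level
    test); ``vocab_counts`` maps each observed word to its total count.
    Per-text counts are derivable via :meth:`per_text_counts` and
    :meth:`text_frequency_moments` (used by the text-level test mode).
    """

    label: str
    texts: list[TokenizedText]
    total_tokens: int = field(init=False)
    vocab_counts: Counter = field(init=False)

    def __post_init__(self) -> None:
        ids = [t.post_id for t in self.texts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate post_id in corpus {self.label!r}")
        counts: Counter = Counter()
        total = 0
        for t in self.texts:
            counts.update(t.tokens)
            total += t.length
        self.total_tokens = total
        self.vocab_counts = counts

    @property
    def n_texts(self) -> int:
        return len(self.texts)

    @property
    def post_ids(self) -> set[str]:
        return {t.post_id for t in self.texts}

    def per_text_counts(self, word: str) -> list[int]:
        """Occurrences of ``word`` in each text, aligned with ``texts``."""
        return [t.tokens.count(word) for t in self.texts]

    def text_frequency_moments(self) -> tuple[dict[str, float], dict[str, float]]:
        """Per-word sums of per-text relative frequencies and their squares.

        Texts of length zero contribute frequency 0. Only words that
        occur somewhere appear as keys; absent words have both sums 0.
        """
        s1: dict[str, float] = {}
        s2: dict[str, float] = {}
        for t in self.texts:
            if t.length == 0:
                continue
            inv = 1.0 / t.length
            for word, c in Counter(t.tokens).items():
                f = c * inv
                s1[word] = s1.get(word, 0.0) + f
                s2[word] = s2.get(word, 0.0) + f * f
        return s1, s2

    def to_tsv(self, path) -> None:
        """Write the count table as TSV (word, count, n_texts_containing)."""
        containing: Counter = Counter()
        for t in self.texts:
            containing.update(set(t.tokens))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("word\tcount\tn_texts_containing\n")
            for word in sorted(self.vocab_counts):
                fh.write(f"{word}\t{self.vocab_counts[word]}\t{containing[word]}\n")


def build_corpus(label: str, tokenized_texts: Sequence[TokenizedText]) -> Corpus:
    """Aggregate tokenized texts into a :class:`Corpus`.

    Raises ``ValueError`` on duplicate post ids.
    """
    return Corpus(label, list(tokenized_texts))
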