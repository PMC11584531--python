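"""Synthetic post collections with the structure the analysis assumes.

The generator emulates a decade of short migraine-forum posts: a
Zipf-distributed background vocabulary, negative-binomial post lengths,
independent per-post drug mentions at configurable prevalences, and
"adverse-event" signal words whose per-token rate is multiplied by a
rate ratio inside the posts that mention the paired drug. One synonym
of each mentioned drug is spliced into the token stream, so drug-corpus
assembly behaves exactly as on real data.

Everything is driven by a single seeded generator, and the same draw
is shared by :func:`simulate` (token-level, used by the Monte Carlo
experiments) and :func:`generate_posts` (rendered title/body posts for
the end-to-end pipeline), so the two views of one seed are identical.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ingest import Post
from .lexicon import DrugLexicon, default_lexicon
from .textproc import Corpus, TokenizedText, build_corpus
from .diffstats import ComparisonResult

__all__ = [
    "SyntheticConfig",
    "SimulatedPosts",
    "RecoveryMetrics",
    "simulate",
    "generate_posts",
    "score_recovery",
]

_EPOCH_2010 = 1262304000  # 2010-01-01T00:00:00Z
_EPOCH_2020 = 1577836800  # 2020-01-01T00:00:00Z

#: Drug-mention prevalences matching the observed extraction fractions
#: (402, 1423, 468 and 73 posts out of 22,467).
STUDY_SCALE_PREVALENCE = {
    "propranolol": 0.0179,
    "topiramate": 0.0633,
    "erenumab": 0.0208,
    "fremanezumab": 0.0032,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All parameters of the synthetic corpus generator.

    Post lengths are negative-binomial with the given mean and
    dispersion (shape) parameter; variance = mean + mean^2/dispersion.
    ``planted_signals`` is a tuple of (drug, word, rate_ratio): inside
    posts mentioning that drug, the word's background per-token rate is
    multiplied by rate_ratio (1 = null). Planted words not already in
    the vocabulary are placed at consecutive Zipf ranks starting at
    ``planted_rank``.

    ``burstiness`` (off by default) draws each post's word distribution
    from a Dirichlet centred on the Zipf background with concentration
    ``burstiness`` x base probabilities, so words clump within posts;
    smaller values are burstier. This stresses the difference between
    token-level and text-level sampling units in the comparison test.
    """

    n_posts: int = 22467
    vocab_size: int = 5000
    zipf_exponent: float = 1.1
    post_length_mean: float = 60.0
    post_length_dispersion: float = 1.2
    drug_prevalence: Mapping[str, float] = field(default_factory=dict)
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    planted_rank: int = 150
    burstiness: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_prevalence", dict(self.drug_prevalence))
        object.__setattr__(self, "planted_signals", tuple(tuple(s) for s in self.planted_signals))
        if self.n_posts < 1 or self.vocab_size < 1:
            raise ValueError("n_posts and vocab_size must be positive")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.post_length_mean <= 0 or self.post_length_dispersion <= 0:
            raise ValueError("post length parameters must be positive")
        if self.burstiness is not None and self.burstiness <= 0:
            raise ValueError("burstiness concentration must be positive")
        for drug, p in self.drug_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {drug!r} must be in [0,1], got {p}")
        for drug, word, ratio in self.planted_signals:
            if drug not in self.drug_prevalence:
                raise ValueError(f"planted signal references unknown drug {drug!r}")
            if ratio < 0:
                raise ValueError(f"rate_ratio must be >= 0, got {ratio}")
            if len(word) < 3 or not all(c in string.ascii_lowercase for c in word):
                raise ValueError(f"planted word {word!r} must be >=3 lowercase letters")

    @classmethod
    def study_scale(
        cls,
        seed: int = 0,
        planted_signals: Sequence[tuple[str, str, float]] = (),
        **overrides,
    ) -> "SyntheticConfig":
        """Preset at the scale of the Reddit r/Migraine extract."""
        return cls(
            drug_prevalence=STUDY_SCALE_PREVALENCE,
            planted_signals=tuple(planted_signals),
            seed=seed,
            **overrides,
        )


def _pseudo_word(i: int) -> str:
    """Deterministic letter-only pseudo-word for vocabulary rank i.

    Enumerates base-26 strings of length 3, then 4, and so on, so every
    word passes the tokenizer's length filter.
    """
    length = 3
    block = 26 ** length
    while i >= block:
        i -= block
        length += 1
        block = 26 ** length
    letters = []
    for _ in range(length):
        letters.append(string.ascii_lowercase[i % 26])
        i //= 26
    return "".join(reversed(letters))


def _build_vocabulary(config: SyntheticConfig, forbidden: set[str]) -> list[str]:
    vocab: list[str] = []
    i = 0
    while len(vocab) < config.vocab_size:
        w = _pseudo_word(i)
        i += 1
        if w not in forbidden:
            vocab.append(w)
    planted = []
    for _, word, _ in config.planted_signals:
        if word not in planted:
            planted.append(word)
    for j, word in enumerate(planted):
        if word in vocab:
            continue
        rank = config.planted_rank + j
        if rank >= config.vocab_size:
            raise ValueError("planted_rank exceeds vocabulary size")
        vocab[rank] = word
    if len(set(vocab)) != len(vocab):
        raise ValueError("vocabulary collision between planted words and background")
    return vocab


def _segment_positions(starts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Flat indices covering [starts[j], starts[j]+lens[j]) for all j."""
    keep = lens > 0
    starts, lens = starts[keep], lens[keep]
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    step = np.ones(total, dtype=np.int64)
    step[0] = starts[0]
    ends = np.cumsum(lens)[:-1]
    step[ends] = starts[1:] - (starts[:-1] + lens[:-1]) + 1
    return np.cumsum(step)


@dataclass
class SimulatedPosts:
    """Token-level view of one simulated collection.

    Background tokens are held as a flat rank array and materialized to
    word lists lazily, per post, so experiments that touch only a
    subset of posts (a drug corpus and one control group) do not pay
    for rendering the full collection.
    """

    config: SyntheticConfig
    lexicon: DrugLexicon
    vocab: list[str]
    post_ids: list[str]
    timestamps: list[int]
    mentions: dict[str, np.ndarray]
    _token_ids: np.ndarray  # flat background token ranks
    _offsets: np.ndarray  # post i owns _token_ids[_offsets[i]:_offsets[i+1]]
    _insertions: dict[int, list[tuple[int, str]]]  # post -> (position, synonym)

    def __post_init__(self) -> None:
        self._vocab_arr = np.array(self.vocab)

    @property
    def n_posts(self) -> int:
        return len(self.post_ids)

    def drug_post_ids(self, drug: str) -> set[str]:
        mask = self.mentions[drug]
        return {self.post_ids[i] for i in np.nonzero(mask)[0]}

    def control_post_ids(self) -> set[str]:
        """Posts mentioning none of the generated drugs."""
        if not self.mentions:
            return set(self.post_ids)
        any_mention = np.logical_or.reduce(list(self.mentions.values()))
        return {self.post_ids[i] for i in np.nonzero(~any_mention)[0]}

    def tokens_for(self, indices: Sequence[int]) -> list[list[str]]:
        """Materialize token lists (with spliced synonyms) for given posts."""
        indices = list(indices)
        if not indices:
            return []
        starts = self._offsets[indices]
        lens = self._offsets[np.asarray(indices) + 1] - starts
        flat = self._vocab_arr[self._token_ids[_segment_positions(starts, lens)]].tolist()
        out = []
        pos = 0
        for i, ln in zip(indices, lens):
            toks = flat[pos: pos + ln]
            pos += ln
            for ins_pos, syn in self._insertions.get(i, ()):
                toks.insert(ins_pos, syn)
            out.append(toks)
        return out

    @property
    def tokens(self) -> list[list[str]]:
        """Token lists for every post (materialized on first access)."""
        cached = getattr(self, "_tokens_cache", None)
        if cached is None:
            cached = self.tokens_for(range(self.n_posts))
            self._tokens_cache = cached
        return cached

    def corpus_for_ids(self, label: str, ids: set[str]) -> Corpus:
        index = {pid: i for i, pid in enumerate(self.post_ids)}
        ordered = sorted(ids)
        token_lists = self.tokens_for([index[pid] for pid in ordered])
        texts = [TokenizedText(pid, toks) for pid, toks in zip(ordered, token_lists)]
        return build_corpus(label, texts)

    def to_posts(self, title_tokens: int = 6) -> list[Post]:
        """Render as title/body posts (the first few tokens become the title)."""
        posts = []
        for pid, ts, toks in zip(self.post_ids, self.timestamps, self.tokens):
            title = " ".join(toks[:title_tokens])
            body = " ".join(toks[title_tokens:])
            posts.append(Post.create(post_id=pid, timestamp=ts, title=title, body=body))
        return posts


def simulate(config: SyntheticConfig, lexicon: DrugLexicon | None = None) -> SimulatedPosts:
    """Draw one collection; bit-reproducible for a fixed config."""
    lexicon = lexicon or default_lexicon()
    drugs = sorted(config.drug_prevalence)
    for d in drugs:
        lexicon.synonyms(d)  # unknown drug -> error
    forbidden = {s for d in lexicon.entries for s in lexicon.entries[d]}
    vocab = _build_vocabulary(config, forbidden)
    rank_of = {w: r for r, w in enumerate(vocab)}

    base = (np.arange(1, config.vocab_size + 1, dtype=float)) ** (-config.zipf_exponent)
    base /= base.sum()

    rng = np.random.default_rng(config.seed)
    n = config.n_posts

    # 1) per-post, per-drug mention indicators
    prev = np.array([config.drug_prevalence[d] for d in drugs])
    if drugs:
        mention_matrix = rng.random((n, len(drugs))) < prev
    else:
        mention_matrix = np.zeros((n, 0), dtype=bool)
    mentions = {d: mention_matrix[:, j].copy() for j, d in enumerate(drugs)}

    # 2) post lengths
    disp = config.post_length_dispersion
    p_nb = disp / (disp + config.post_length_mean)
    lengths = rng.negative_binomial(disp, p_nb, size=n).astype(np.int64)
    lengths = np.maximum(lengths, 1)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    # 3) background tokens, drawn per boost class (posts sharing the same
    #    set of signal-carrying mentioned drugs share a distribution)
    signal_drugs = sorted({d for d, _, _ in config.planted_signals})
    sig = np.zeros(n, dtype=np.int64)
    for j, d in enumerate(signal_drugs):
        sig |= mentions[d].astype(np.int64) << j
    def class_probs(mask_val: int) -> np.ndarray:
        probs = base.copy()
        for j, d in enumerate(signal_drugs):
            if mask_val >> j & 1:
                for drug, word, ratio in config.planted_signals:
                    if drug == d:
                        probs[rank_of[word]] *= ratio
        return probs / probs.sum()

    all_ids = np.empty(total, dtype=np.int64)
    if config.burstiness is None:
        for mask_val in np.unique(sig):
            sel = np.nonzero(sig == mask_val)[0]
            probs = class_probs(int(mask_val))
            n_tok = int(lengths[sel].sum())
            if n_tok == 0:
                continue
            draw = rng.choice(config.vocab_size, size=n_tok, p=probs)
            all_ids[_segment_positions(offsets[sel], lengths[sel])] = draw
    else:
        # bursty regime: each post gets its own word distribution drawn
        # around the (possibly boosted) background
        probs_by_class = {int(m): class_probs(int(m)) for m in np.unique(sig)}
        for i in range(n):
            theta = rng.dirichlet(config.burstiness * probs_by_class[int(sig[i])])
            total_theta = theta.sum()
            if not np.isfinite(total_theta) or total_theta <= 0:
                theta = probs_by_class[int(sig[i])]
            else:
                theta = theta / total_theta
            all_ids[offsets[i]: offsets[i + 1]] = rng.choice(
                config.vocab_size, size=int(lengths[i]), p=theta
            )

    # 4) splice one synonym of each mentioned drug into the token stream
    #    (recorded as sequential insertions, applied on materialization)
    sorted_syns = {d: sorted(lexicon.synonyms(d)) for d in drugs}
    insertions: dict[int, list[tuple[int, str]]] = {}
    for i in np.nonzero(mention_matrix.any(axis=1))[0]:
        i = int(i)
        cur_len = int(lengths[i])
        for j, d in enumerate(drugs):
            if not mention_matrix[i, j]:
                continue
            syns = sorted_syns[d]
            syn = syns[int(rng.integers(len(syns)))]
            pos = int(rng.integers(cur_len + 1))
            insertions.setdefault(i, []).append((pos, syn))
            cur_len += 1

    span = _EPOCH_2020 - _EPOCH_2010
    timestamps = [_EPOCH_2010 + (i * span) // n for i in range(n)]
    post_ids = [f"s{i:06d}" for i in range(n)]
    return SimulatedPosts(
        config=config,
        lexicon=lexicon,
        vocab=vocab,
        post_ids=post_ids,
        timestamps=timestamps,
        mentions=mentions,
        _token_ids=all_ids,
        _offsets=offsets,
        _insertions=insertions,
    )


def generate_posts(config: SyntheticConfig, lexicon: DrugLexicon | None = None) -> list[Post]:
    """Generate a rendered post collection (same draw as :func:`simulate`)."""
    return simulate(config, lexicon).to_posts()


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well a comparison recovered the planted signal words.

    ``precision`` is None (undefined) when nothing was retained but
    signals were planted; ``false_flag_rate`` is the fraction of tested
    non-planted words that were retained.
    """

    recall: float
    precision: float | None
    false_flag_rate: float


def score_recovery(result: ComparisonResult, planted_words: set[str]) -> RecoveryMetrics:
    retained = set(result.retained)
    planted = set(planted_words)
    tp = len(retained & planted)
    recall = tp / len(planted) if planted else 1.0
    if retained:
        precision = tp / len(retained)
    else:
        precision = 1.0 if not planted else None
    tested = set(result.table["word"])
    nonplanted = tested - planted
    false_flags = len(retained - planted)
    false_flag_rate = false_flags / len(nonplanted) if nonplanted else 0.0
    return RecoveryMetrics(recall=recall, precision=precision, false_flag_rate=false_flag_rate)
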