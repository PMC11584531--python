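"""Per-word Welch t-tests between corpora with BH retention.

For each word q shared or distinct between corpus S and corpus T, the
test asks whether q's mean frequency is greater in S than in T
(one-tailed). Two sampling-unit modes are supported:

``token`` (default)
    Each token position is a Bernoulli trial for "is this token q".
    With n_i total tokens and count_i occurrences, the mean frequency
    is x_i = count_i / n_i and the variance is the unbiased sample
    variance of the 0/1 indicator vector, x_i (1 - x_i) n_i / (n_i - 1).
    This reproduces exactly the textbook Welch statistic computed on
    the materialized indicator vectors.

``text``
    Each post is a sampling unit; the observation is the word's
    relative frequency within the post, with the unbiased sample
    variance across posts and n_i = number of posts. This is robust to
    burstiness (a word occurring many times in one long post).

The significance decision is the literal rule t > t_threshold
(default 1.73, a one-tailed P<.05-style cutoff); p-values from the
Welch–Satterthwaite t distribution are computed for ranking and for the
Benjamini–Hochberg step-up procedure. Two BH scopes are provided:
``significant_only`` applies BH to the ranked list of already
significant words (the two-stage procedure this pipeline replicates),
``all_words`` is the standard FDR-controlling variant over the full
tested vocabulary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import json

import numpy as np
import pandas as pd
from scipy import stats

from .textproc import Corpus

__all__ = [
    "TestConfig",
    "WordStat",
    "ComparisonResult",
    "welch_t",
    "compare_corpora",
    "bh_retain",
]


@dataclass(frozen=True)
class TestConfig:
    """Knobs of the corpus-comparison test.

    t_threshold is the one-tailed significance cutoff applied to the t
    statistic itself; bh_q the FDR level; min_total_count drops words
    rarer than the floor (across both corpora) before testing.
    """

    mode: str = "token"
    t_threshold: float = 1.73
    bh_q: float = 0.05
    bh_scope: str = "significant_only"
    min_total_count: int = 1

    def __post_init__(self) -> None:
        if self.mode not in {"token", "text"}:
            raise ValueError(f"mode must be 'token' or 'text', got {self.mode!r}")
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be positive")
        if not (0 < self.bh_q <= 1):
            raise ValueError("bh_q must be in (0, 1]")
        if self.bh_scope not in {"significant_only", "all_words"}:
            raise ValueError(f"bh_scope must be 'significant_only' or 'all_words', got {self.bh_scope!r}")
        if self.min_total_count < 1:
            raise ValueError("min_total_count must be >= 1")


@dataclass(frozen=True)
class WordStat:
    """Full per-word comparison record."""

    word: str
    count1: int
    count2: int
    n1: int
    n2: int
    x1: float
    x2: float
    var1: float
    var2: float
    t_stat: float
    p_value: float
    significant: bool
    retained: bool


def _indicator_moments(count: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and unbiased variance of the 0/1 token-indicator vector."""
    x = count / n
    if n >= 2:
        var = x * (1.0 - x) * (n / (n - 1.0))
    else:
        var = np.zeros_like(x)
    return x, var


def _welch_from_moments(
    x1: np.ndarray, var1: np.ndarray, n1: int, x2: np.ndarray, var2: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t and upper-tail p from per-group moments.

    Degenerate case var1 = var2 = 0: t is 0 for equal means, +/-inf
    otherwise; p follows from the survival function (0.5, 0, 1).
    """
    v1 = var1 / n1
    v2 = var2 / n2
    se2 = v1 + v2
    diff = x1 - x2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        den = np.zeros_like(se2)
        if n1 >= 2:
            den = den + v1 * v1 / (n1 - 1.0)
        if n2 >= 2:
            den = den + v2 * v2 / (n2 - 1.0)
        df = se2 * se2 / den
    zero_se = se2 == 0
    if np.any(zero_se):
        with np.errstate(invalid="ignore"):
            t = np.where(zero_se, np.sign(diff) * np.inf, t)
        t = np.where(zero_se & (diff == 0), 0.0, t)
    df = np.where(~np.isfinite(df) | (df <= 0), np.inf, df)
    p = stats.t.sf(t, df)
    return t, p


def welch_t(
    count1: int,
    n1: int,
    count2: int,
    n2: int,
    mode: str = "token",
    per_text_freqs_s: Sequence[float] | None = None,
    per_text_freqs_t: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Welch t statistic and one-tailed (upper) p for a single word.

    Token mode needs only the counts and token totals. Text mode needs
    the per-text relative-frequency vectors, whose lengths are the
    corpus sizes n1 and n2.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("corpus sizes must be positive")
    if mode == "token":
        x1, var1 = _indicator_moments(np.asarray([count1], dtype=float), n1)
        x2, var2 = _indicator_moments(np.asarray([count2], dtype=float), n2)
    elif mode == "text":
        if per_text_freqs_s is None or per_text_freqs_t is None:
            raise ValueError("text mode requires per-text frequency vectors")
        fs = np.asarray(per_text_freqs_s, dtype=float)
        ft = np.asarray(per_text_freqs_t, dtype=float)
        if len(fs) != n1 or len(ft) != n2:
            raise ValueError("per-text frequency vectors must have lengths n1 and n2")
        x1 = np.asarray([fs.mean()])
        x2 = np.asarray([ft.mean()])
        var1 = np.asarray([fs.var(ddof=1) if n1 >= 2 else 0.0])
        var2 = np.asarray([ft.var(ddof=1) if n2 >= 2 else 0.0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    t, p = _welch_from_moments(x1, var1, n1, x2, var2, n2)
    return float(t[0]), float(p[0])


def bh_retain(p_values: Sequence[float], q: float) -> int:
    """Benjamini–Hochberg step-up on an ascending p-value list.

    Returns k, the largest rank i with p_(i) <= i q / m (0 if none);
    the first k entries of the ranked list are retained.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return 0
    if np.any(np.diff(p) < 0):
        raise ValueError("p_values must be sorted ascending")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_values must lie in [0, 1]")
    ranks = np.arange(1, m + 1)
    passing = np.nonzero(p <= ranks * q / m)[0]
    return int(passing[-1] + 1) if passing.size else 0


@dataclass
class ComparisonResult:
    """Outcome of one corpus-pair comparison.

    ``table`` holds every tested word in rank order (ascending p, ties
    broken by descending t then word); ``retained`` is the ordered
    keyword list that survives BH.
    """

    label_s: str
    label_t: str
    n1: int
    n2: int
    config: TestConfig
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "word"].tolist()

    @property
    def significant_words(self) -> list[str]:
        return self.table.loc[self.table["significant"], "word"].tolist()

    def word_stat(self, word: str) -> WordStat:
        row = self.table.loc[self.table["word"] == word]
        if row.empty:
            raise KeyError(word)
        r = row.iloc[0]
        return WordStat(
            word=r["word"], count1=int(r["count1"]), count2=int(r["count2"]),
            n1=self.n1, n2=self.n2, x1=float(r["x1"]), x2=float(r["x2"]),
            var1=float(r["var1"]), var2=float(r["var2"]), t_stat=float(r["t_stat"]),
            p_value=float(r["p_value"]), significant=bool(r["significant"]),
            retained=bool(r["retained"]),
        )

    def to_tsv(self, path) -> None:
        cols = ["word", "count1", "count2", "x1", "x2", "t_stat", "p_value", "significant", "retained"]
        out = self.table[cols].copy()
        for c in ("x1", "x2", "t_stat", "p_value"):
            out[c] = out[c].map(lambda v: format(v, ".10g"))
        out.to_csv(path, sep="\t", index=False)

    def metadata_sidecar(self) -> dict:
        return {
            "label_s": self.label_s,
            "label_t": self.label_t,
            "n1": self.n1,
            "n2": self.n2,
            "config": asdict(self.config),
            "n_words_tested": int(len(self.table)),
            "n_significant": int(self.table["significant"].sum()),
            "n_retained": int(self.table["retained"].sum()),
            **self.metadata,
        }

    def write_metadata(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata_sidecar(), fh, indent=2, sort_keys=True)


def compare_corpora(s: Corpus, t: Corpus, config: TestConfig | None = None) -> ComparisonResult:
    """Test every word of the union vocabulary for excess frequency in S.

    Requires the two corpora to be built from disjoint post sets
    (shared posts must have been removed upstream).
    """
    config = config or TestConfig()
    if not s.texts or not t.texts:
        raise ValueError("both corpora must contain at least one text")
    overlap = s.post_ids & t.post_ids
    if overlap:
        raise ValueError(f"corpora share {len(overlap)} post ids; remove shared posts first")

    words = sorted(set(s.vocab_counts) | set(t.vocab_counts))
    count1 = np.array([s.vocab_counts.get(w, 0) for w in words], dtype=float)
    count2 = np.array([t.vocab_counts.get(w, 0) for w in words], dtype=float)
    keep = (count1 + count2) >= config.min_total_count
    words = [w for w, k in zip(words, keep) if k]
    count1, count2 = count1[keep], count2[keep]

    if config.mode == "token":
        n1, n2 = s.total_tokens, t.total_tokens
        if n1 == 0 or n2 == 0:
            raise ValueError("token mode requires non-empty corpora")
        x1, var1 = _indicator_moments(count1, n1)
        x2, var2 = _indicator_moments(count2, n2)
    else:
        n1, n2 = s.n_texts, t.n_texts
        s1_s, s2_s = s.text_frequency_moments()
        s1_t, s2_t = t.text_frequency_moments()
        sum1 = np.array([s1_s.get(w, 0.0) for w in words])
        sq1 = np.array([s2_s.get(w, 0.0) for w in words])
        sum2 = np.array([s1_t.get(w, 0.0) for w in words])
        sq2 = np.array([s2_t.get(w, 0.0) for w in words])
        x1 = sum1 / n1
        x2 = sum2 / n2
        var1 = np.clip((sq1 - n1 * x1 * x1) / (n1 - 1.0), 0.0, None) if n1 >= 2 else np.zeros_like(x1)
        var2 = np.clip((sq2 - n2 * x2 * x2) / (n2 - 1.0), 0.0, None) if n2 >= 2 else np.zeros_like(x2)

    t_stat, p_value = _welch_from_moments(x1, var1, n1, x2, var2, n2)
    significant = t_stat > config.t_threshold

    table = pd.DataFrame(
        {
            "word": words,
            "count1": count1.astype(int),
            "count2": count2.astype(int),
            "x1": x1,
            "x2": x2,
            "var1": var1,
            "var2": var2,
            "t_stat": t_stat,
            "p_value": p_value,
            "significant": significant,
        }
    )
    # rank order: ascending p, ties by descending t then word
    table = table.sort_values(
        ["p_value", "t_stat", "word"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)

    retained = np.zeros(len(table), dtype=bool)
    if config.bh_scope == "significant_only":
        sig_idx = np.nonzero(table["significant"].to_numpy())[0]
        k = bh_retain(table["p_value"].to_numpy()[sig_idx], config.bh_q)
        retained[sig_idx[:k]] = True
    else:
        p_sorted = table["p_value"].to_numpy()  # already ascending
        k = bh_retain(p_sorted, config.bh_q)
        if k > 0:
            crit = p_sorted[k - 1]
            retained = table["significant"].to_numpy() & (table["p_value"].to_numpy() <= crit)
    table["retained"] = retained

    return ComparisonResult(
        label_s=s.label,
        label_t=t.label,
        n1=n1,
        n2=n2,
        config=config,
        table=table,
        metadata={
            "total_tokens_s": s.total_tokens,
            "total_tokens_t": t.total_tokens,
            "n_texts_s": s.n_texts,
            "n_texts_t": t.n_texts,
        },
    )
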