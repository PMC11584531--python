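import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pharmakeyword.diffstats import (
    TestConfig,
    bh_retain,
    compare_corpora,
    welch_t,
)
from pharmakeyword.textproc import TokenizedText, build_corpus

from conftest import corpus_of


def indicator_welch(count1, n1, count2, n2):
    """Independent oracle: materialize the 0/1 token-indicator vectors and
    apply the textbook Welch test (scipy, unequal variances, upper tail)."""
    a = np.concatenate([np.ones(count1), np.zeros(n1 - count1)])
    b = np.concatenate([np.ones(count2), np.zeros(n2 - count2)])
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


class TestWelchToken:
    def test_frozen_example(self):
        # count1=5/n1=100 vs count2=1/n2=200, verified against the
        # indicator-vector oracle below
        t, p = welch_t(5, 100, 1, 200)
        assert t == pytest.approx(2.0028743727144844, rel=1e-12)
        assert p == pytest.approx(0.02383151575981076, rel=1e-12)

    def test_equal_frequencies_give_zero(self):
        t, _ = welch_t(5, 100, 10, 200)
        assert t == 0.0

    def test_swap_negates_t(self):
        t1, _ = welch_t(7, 50, 2, 80)
        t2, _ = welch_t(2, 80, 7, 50)
        assert t1 == pytest.approx(-t2, rel=1e-12)
        assert t1 > 0

    def test_matches_indicator_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(2, 21, size=2)
            c1, c2 = rng.integers(1, n1), rng.integers(1, n2)
            t_ref, p_ref = indicator_welch(c1, n1, c2, n2)
            t, p = welch_t(int(c1), int(n1), int(c2), int(n2))
            assert t == pytest.approx(t_ref, rel=1e-12, abs=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-12, abs=1e-12)

    def test_degenerate_zero_variance(self):
        t, p = welch_t(3, 3, 0, 5)  # all tokens vs none: infinite separation
        assert t == np.inf and p == 0.0
        t, p = welch_t(0, 5, 3, 3)
        assert t == -np.inf and p == 1.0
        t, p = welch_t(5, 5, 3, 3)  # both constant, equal means
        assert t == 0.0 and p == 0.5

    def test_zero_length_corpus_rejected(self):
        with pytest.raises(ValueError):
            welch_t(0, 0, 1, 10)


class TestWelchText:
    def test_matches_scipy_on_frequency_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            fs = rng.random(rng.integers(2, 10))
            ft = rng.random(rng.integers(2, 10))
            ref = stats.ttest_ind(fs, ft, equal_var=False, alternative="greater")
            t, p = welch_t(0, len(fs), 0, len(ft), mode="text",
                           per_text_freqs_s=fs, per_text_freqs_t=ft)
            assert t == pytest.approx(float(ref.statistic), rel=1e-12)
            assert p == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_requires_frequency_vectors(self):
        with pytest.raises(ValueError):
            welch_t(1, 2, 1, 2, mode="text")


class TestBHRetain:
    def test_step_up_example(self):
        assert bh_retain([0.01, 0.02, 0.04, 0.05], 0.05) == 4

    def test_single_high_p(self):
        assert bh_retain([1.0], 0.04) == 0

    def test_empty_list(self):
        assert bh_retain([], 0.05) == 0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            bh_retain([0.5, 0.1], 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_retain([-0.1, 0.5], 0.05)

    @given(st.lists(st.floats(0, 1), max_size=40), st.sampled_from([0.01, 0.05, 0.1]))
    @settings(max_examples=200, derandomize=True)
    def test_matches_statsmodels_fdr(self, ps, q):
        from statsmodels.stats.multitest import multipletests

        ps = sorted(ps)
        k = bh_retain(ps, q)
        if ps:
            reject, *_ = multipletests(ps, alpha=q, method="fdr_bh")
            assert k == int(reject.sum())
        else:
            assert k == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_q(self, ps):
        ps = sorted(ps)
        ks = [bh_retain(ps, q) for q in (0.01, 0.05, 0.10)]
        assert ks == sorted(ks)


def random_corpus_pair(seed, n_texts=6, n_tokens=10, vocab=("aaa", "bbb", "ccc", "ddd")):
    rng = np.random.default_rng(seed)
    def make(label, prefix):
        texts = [
            TokenizedText(f"{prefix}{i}", rng.choice(vocab, size=rng.integers(1, n_tokens)))
            for i in range(n_texts)
        ]
        return build_corpus(label, texts)
    return make("S", "s"), make("T", "t")


class TestCompareCorpora:
    def test_identical_token_counts_all_zero_t(self):
        s = corpus_of("S", ["abc", "abc", "def"], prefix="s")
        t = corpus_of("T", ["abc", "abc", "def"], prefix="t")
        result = compare_corpora(s, t)
        assert (result.table["t_stat"] == 0).all()
        assert result.retained == []

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("mode", ["token", "text"])
    def test_antisymmetry(self, seed, mode):
        s, t = random_corpus_pair(seed)
        cfg = TestConfig(mode=mode)
        fwd = compare_corpora(s, t, cfg).table.set_index("word")["t_stat"]
        rev = compare_corpora(t, s, cfg).table.set_index("word")["t_stat"]
        aligned = fwd.sort_index() + rev.sort_index()
        finite = aligned[np.isfinite(aligned)]
        assert (finite.abs() < 1e-12).all()

    @pytest.mark.parametrize("scope", ["significant_only", "all_words"])
    def test_retained_nested_in_q(self, scope):
        s, t = random_corpus_pair(3, n_texts=20, n_tokens=30)
        retained = {
            q: set(compare_corpora(s, t, TestConfig(bh_q=q, bh_scope=scope)).retained)
            for q in (0.01, 0.05, 0.10)
        }
        assert retained[0.01] <= retained[0.05] <= retained[0.10]

    def test_retained_implies_significant_above_threshold(self):
        s, t = random_corpus_pair(5, n_texts=25, n_tokens=40)
        result = compare_corpora(s, t)
        tab = result.table
        assert (tab.loc[tab["retained"], "t_stat"] > result.config.t_threshold).all()
        assert not (tab["retained"] & ~tab["significant"]).any()

    def test_rank_order_and_tie_break(self):
        # identical counts for two words -> identical p; lexicographic order
        s = corpus_of("S", ["bbb", "aaa", "bbb", "aaa", "ccc"], prefix="s")
        t = corpus_of("T", ["ccc", "ccc", "ccc"], prefix="t")
        table = compare_corpora(s, t).table
        ps = table["p_value"].to_numpy()
        assert (np.diff(ps) >= 0).all()
        tied = table[table["word"].isin(["aaa", "bbb"])]
        assert tied["p_value"].nunique() == 1
        assert tied["word"].tolist() == ["aaa", "bbb"]

    def test_min_total_count_floor(self):
        s = corpus_of("S", ["aaa", "aaa", "bbb"], prefix="s")
        t = corpus_of("T", ["aaa"], prefix="t")
        result = compare_corpora(s, t, TestConfig(min_total_count=2))
        assert set(result.table["word"]) == {"aaa"}

    def test_overlapping_post_ids_rejected(self):
        s = corpus_of("S", ["aaa"], prefix="x")
        t = corpus_of("T", ["bbb"], prefix="x")
        with pytest.raises(ValueError, match="share"):
            compare_corpora(s, t)

    def test_empty_corpus_rejected(self):
        s = corpus_of("S", ["aaa"])
        empty = build_corpus("T", [])
        with pytest.raises(ValueError):
            compare_corpora(s, empty)

    def test_significant_only_scope_uses_significant_list_length(self):
        # hand-built check of the two-stage rule: BH m equals the number
        # of significant words, not the vocabulary size
        s, t = random_corpus_pair(9, n_texts=30, n_tokens=40)
        result = compare_corpora(s, t, TestConfig(bh_scope="significant_only"))
        sig_p = result.table.loc[result.table["significant"], "p_value"].to_numpy()
        expected_k = bh_retain(np.sort(sig_p), result.config.bh_q)
        assert len(result.retained) == expected_k

    def test_tsv_and_metadata_outputs(self, tmp_path):
        s, t = random_corpus_pair(1)
        result = compare_corpora(s, t)
        result.to_tsv(tmp_path / "out.tsv")
        result.write_metadata(tmp_path / "out.json")
        header = (tmp_path / "out.tsv").read_text().splitlines()[0]
        assert header.split("\t") == [
            "word", "count1", "count2", "x1", "x2", "t_stat", "p_value",
            "significant", "retained",
        ]

    def test_word_stat_invariants(self):
        s, t = random_corpus_pair(2)
        result = compare_corpora(s, t)
        for word in result.table["word"].head(5):
            ws = result.word_stat(word)
            assert 0.0 <= ws.x1 <= 1.0 and 0.0 <= ws.x2 <= 1.0
            if np.isfinite(ws.t_stat) and ws.t_stat != 0:
                assert np.sign(ws.t_stat) == np.sign(ws.x1 - ws.x2)
            assert ws.retained <= ws.significant


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mode": "char"},
            {"t_threshold": 0.0},
            {"bh_q": 0.0},
            {"bh_q": 1.5},
            {"bh_scope": "everything"},
            {"min_total_count": 0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TestConfig(**kwargs)
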