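import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmakeyword.diffstats import ComparisonResult, TestConfig, compare_corpora
from pharmakeyword.lexicon import build_corpora
from pharmakeyword.synthetic import (
    RecoveryMetrics,
    SyntheticConfig,
    generate_posts,
    score_recovery,
    simulate,
)
from pharmakeyword.textproc import tokenize


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_posts": 0},
            {"zipf_exponent": 0.0},
            {"post_length_mean": -1.0},
            {"drug_prevalence": {"topiramate": 1.5}},
            {"planted_signals": (("unknown", "appetite", 2.0),)},
            {
                "drug_prevalence": {"topiramate": 0.1},
                "planted_signals": (("topiramate", "ab", 2.0),),
            },
            {
                "drug_prevalence": {"topiramate": 0.1},
                "planted_signals": (("topiramate", "appetite", -1.0),),
            },
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)

    def test_study_scale_preset_prevalences(self):
        cfg = SyntheticConfig.study_scale()
        assert cfg.n_posts == 22467
        assert cfg.drug_prevalence["topiramate"] == pytest.approx(0.0633)
        assert cfg.drug_prevalence["fremanezumab"] == pytest.approx(0.0032)


class TestGeneration:
    def test_bit_reproducible_under_fixed_seed(self, small_config):
        a, b = simulate(small_config), simulate(small_config)
        assert a.post_ids == b.post_ids
        assert a.tokens == b.tokens
        for drug in a.mentions:
            assert (a.mentions[drug] == b.mentions[drug]).all()
        assert generate_posts(small_config) == generate_posts(small_config)

    def test_rendered_posts_retokenize_to_planted_tokens(self, small_config):
        sim = simulate(small_config)
        posts = simulate(small_config).to_posts()
        for post, toks in zip(posts, sim.tokens):
            assert tokenize(post.text) == toks

    def test_mention_flags_agree_with_lexicon_scan(self, small_config, lexicon):
        sim = simulate(small_config)
        posts = sim.to_posts()
        assignment = build_corpora(posts, lexicon, sorted(small_config.drug_prevalence))
        for drug in small_config.drug_prevalence:
            assert assignment.drug_corpora[drug] == sim.drug_post_ids(drug)
        assert assignment.control_pool == sim.control_post_ids()

    def test_no_drug_prevalence_all_controls(self):
        cfg = SyntheticConfig(n_posts=50, vocab_size=100, seed=3)
        sim = simulate(cfg)
        assert sim.control_post_ids() == set(sim.post_ids)

    def test_realized_prevalence_within_binomial_99_interval(self):
        cfg = SyntheticConfig.study_scale(seed=5)
        sim = simulate(cfg)
        n = cfg.n_posts
        for drug, p in cfg.drug_prevalence.items():
            observed = len(sim.drug_post_ids(drug))
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= observed <= hi, drug

    def test_zipf_marginals_top20_within_5pct(self):
        cfg = SyntheticConfig(n_posts=10_000, vocab_size=2000, seed=9)
        sim = simulate(cfg)
        counts = np.bincount(sim._token_ids, minlength=cfg.vocab_size)
        total = counts.sum()
        expected = np.arange(1, cfg.vocab_size + 1, dtype=float) ** -cfg.zipf_exponent
        expected /= expected.sum()
        rel_err = np.abs(counts[:20] / total - expected[:20]) / expected[:20]
        assert rel_err.max() < 0.05

    def test_planted_word_sits_at_configured_rank(self, small_config):
        sim = simulate(small_config)
        assert sim.vocab[small_config.planted_rank] == "appetite"

    def test_timestamps_span_study_window(self, small_config):
        posts = generate_posts(small_config)
        ts = [p.timestamp for p in posts]
        assert min(ts) >= 1262304000 and max(ts) < 1577836800
        assert ts == sorted(ts)


def fake_result(retained, tested):
    table = pd.DataFrame(
        {
            "word": tested,
            "retained": [w in retained for w in tested],
            "significant": [w in retained for w in tested],
        }
    )
    return ComparisonResult(
        label_s="s", label_t="t", n1=10, n2=10, config=TestConfig(), table=table
    )


class TestScoreRecovery:
    def test_partial_precision(self):
        m = score_recovery(fake_result(["appetite", "taste"], ["appetite", "taste", "zzz"]), {"appetite"})
        assert m.recall == 1.0
        assert m.precision == 0.5
        assert m.false_flag_rate == pytest.approx(0.5)  # "taste" of {"taste","zzz"}

    def test_nothing_retained(self):
        m = score_recovery(fake_result([], ["appetite", "zzz"]), {"appetite"})
        assert m.recall == 0.0
        assert m.precision is None
        assert m.false_flag_rate == 0.0

    def test_perfect_recovery(self):
        m = score_recovery(fake_result(["appetite"], ["appetite", "zzz"]), {"appetite"})
        assert m.recall == 1.0 and m.precision == 1.0 and m.false_flag_rate == 0.0

    def test_null_case_nothing_planted(self):
        m = score_recovery(fake_result([], ["zzz"]), set())
        assert m.recall == 1.0 and m.precision == 1.0


class TestBurstiness:
    def test_bursty_null_inflates_token_mode_but_not_text_mode(self):
        """Within-post word clumping violates the token-level iid
        assumption: under a null comparison the token-mode test flags
        far more words than its nominal rate, while the text-level
        sampling unit stays close to nominal."""
        from pharmakeyword.lexicon import partition_controls

        cfg = SyntheticConfig(n_posts=300, vocab_size=200, post_length_mean=40.0,
                              burstiness=20.0, seed=5)
        sim = simulate(cfg)
        groups = partition_controls(sim.control_post_ids(), 2, seed=5)
        g1 = sim.corpus_for_ids("g1", groups[0])
        g2 = sim.corpus_for_ids("g2", groups[1])
        n_token = int(compare_corpora(g1, g2, TestConfig(mode="token")).table["significant"].sum())
        n_text = int(compare_corpora(g1, g2, TestConfig(mode="text")).table["significant"].sum())
        assert n_token > 2 * n_text

    def test_bursty_generation_reproducible(self):
        cfg = SyntheticConfig(n_posts=50, vocab_size=100, burstiness=5.0, seed=2)
        assert simulate(cfg).tokens == simulate(cfg).tokens

    def test_invalid_burstiness_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(burstiness=0.0)


class TestPlantedSignalDetection:
    def test_planted_word_retained_in_drug_vs_control(self, small_config, lexicon):
        # single-collection check; the seed-averaged power study lives in
        # the experiments module
        sim = simulate(small_config)
        from pharmakeyword.lexicon import partition_controls

        groups = partition_controls(sim.control_post_ids(), 2, seed=11)
        s = sim.corpus_for_ids("topiramate", sim.drug_post_ids("topiramate"))
        t = sim.corpus_for_ids("control", groups[0])
        result = compare_corpora(s, t, TestConfig(bh_scope="all_words"))
        assert "appetite" in result.retained
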