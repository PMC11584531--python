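"""Monte Carlo validation experiments for the comparison pipeline.

These experiments characterize the statistical behaviour of the
corpus-comparison test on synthetic collections drawn at the scale of
the real extract (~22.5k posts):

* null calibration — two control groups share one generating
  distribution, so any retained keyword is a false discovery;
* planted-signal recovery — power to retain a word whose rate is
  elevated by a known ratio inside one drug's posts;
* corpus-size asymmetry — the same signal is easier to recover for a
  commonly-mentioned drug than for a rarely-mentioned one.

The experiments use the statistically standard BH scope (``all_words``)
so that the false-discovery rate is actually controlled at bh_q; under
the replicated two-stage scope (``significant_only``) the null retains
large word lists by design. Each run re-simulates a full collection
from a seed derived from ``base_seed``, builds corpora with the same
partitioning code as the pipeline, and scores recovery of the planted
words.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .diffstats import ComparisonResult, TestConfig, compare_corpora
from .lexicon import partition_controls
from .synthetic import SimulatedPosts, SyntheticConfig, score_recovery, simulate

__all__ = [
    "CalibrationResult",
    "RecoveryResult",
    "null_calibration",
    "recovery_experiment",
    "recovery_curve",
    "corpus_size_asymmetry",
]

_EXPERIMENT_CONFIG = TestConfig(bh_scope="all_words")


def derive_seed(base_seed: int, tag: int, index: int) -> int:
    """Independent per-run seed below 2^31, reproducible from base_seed."""
    return int(np.random.SeedSequence([base_seed, tag, index]).generate_state(1)[0] % (2**31))


def _control_corpora(sim: SimulatedPosts, k: int, seed: int):
    groups = partition_controls(sim.control_post_ids(), k, seed)
    return [sim.corpus_for_ids(f"group{i + 1}", g) for i, g in enumerate(groups)]


def drug_vs_group(
    sim: SimulatedPosts, drug: str, group_index: int, k: int, seed: int,
    test_config: TestConfig,
) -> ComparisonResult:
    """One drug-vs-control comparison on a simulated collection."""
    groups = partition_controls(sim.control_post_ids(), k, seed)
    s = sim.corpus_for_ids(drug, sim.drug_post_ids(drug))
    t = sim.corpus_for_ids(f"group{group_index}", groups[group_index - 1])
    return compare_corpora(s, t, test_config)


@dataclass
class CalibrationResult:
    """Null-comparison behaviour over repeated seeded runs."""

    n_runs: int
    empty_fraction: float  # runs where the retained list was empty
    mean_significant_fraction: float  # pre-BH fraction of words with t > threshold
    runs: pd.DataFrame  # seed, n_tested, n_significant, n_retained


def null_calibration(
    n_runs: int = 200,
    base_seed: int = 0,
    config: SyntheticConfig | None = None,
    test_config: TestConfig = _EXPERIMENT_CONFIG,
) -> CalibrationResult:
    """Compare control group 1 against control group 2, repeatedly.

    Both groups are drawn from the identical background distribution,
    so every retained keyword is a type-I error. With BH over the full
    tested vocabulary at level q, the retained list should be empty in
    at least a fraction 1 - q of runs.
    """
    base_config = config or SyntheticConfig.study_scale()
    records = []
    for i in range(n_runs):
        seed = derive_seed(base_seed, 1, i)
        sim = simulate(replace(base_config, seed=seed))
        group1, group2 = _control_corpora(sim, 4, seed)[:2]
        result = compare_corpora(group1, group2, test_config)
        records.append(
            {
                "seed": seed,
                "n_tested": len(result.table),
                "n_significant": int(result.table["significant"].sum()),
                "n_retained": len(result.retained),
            }
        )
    runs = pd.DataFrame(records)
    return CalibrationResult(
        n_runs=n_runs,
        empty_fraction=float((runs["n_retained"] == 0).mean()),
        mean_significant_fraction=float((runs["n_significant"] / runs["n_tested"]).mean()),
        runs=runs,
    )


@dataclass
class RecoveryResult:
    """Planted-signal recovery over repeated seeded runs."""

    rate_ratio: float
    n_runs: int
    mean_recall: float
    mean_precision: float | None  # averaged over runs where defined
    mean_false_flag_rate: float
    recalls: list[float]


def recovery_experiment(
    rate_ratio: float = 8.0,
    n_runs: int = 100,
    base_seed: int = 0,
    drug: str = "topiramate",
    word: str = "appetite",
    group_index: int = 2,
    config: SyntheticConfig | None = None,
    test_config: TestConfig = _EXPERIMENT_CONFIG,
    seed_tag: int = 2,
) -> RecoveryResult:
    """Plant one elevated word in a drug's posts and measure its recovery
    in the drug-vs-control comparison."""
    base_config = config or SyntheticConfig.study_scale()
    recalls, precisions, false_flags = [], [], []
    for i in range(n_runs):
        seed = derive_seed(base_seed, seed_tag, i)
        cfg = replace(
            base_config, seed=seed, planted_signals=((drug, word, float(rate_ratio)),)
        )
        sim = simulate(cfg)
        result = drug_vs_group(sim, drug, group_index, 4, seed, test_config)
        metrics = score_recovery(result, {word})
        recalls.append(metrics.recall)
        false_flags.append(metrics.false_flag_rate)
        if metrics.precision is not None:
            precisions.append(metrics.precision)
    return RecoveryResult(
        rate_ratio=float(rate_ratio),
        n_runs=n_runs,
        mean_recall=float(np.mean(recalls)),
        mean_precision=float(np.mean(precisions)) if precisions else None,
        mean_false_flag_rate=float(np.mean(false_flags)),
        recalls=recalls,
    )


def recovery_curve(
    rate_ratios: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    n_runs: int = 50,
    base_seed: int = 0,
    **kwargs,
) -> dict[float, RecoveryResult]:
    """Recovery at several rate ratios with paired seeds across ratios."""
    return {
        r: recovery_experiment(
            rate_ratio=r, n_runs=n_runs, base_seed=base_seed, seed_tag=3, **kwargs
        )
        for r in rate_ratios
    }


def corpus_size_asymmetry(
    rate_ratio: float = 4.0,
    n_runs: int = 100,
    base_seed: int = 0,
    word: str = "nausea",
    config: SyntheticConfig | None = None,
    test_config: TestConfig = _EXPERIMENT_CONFIG,
) -> tuple[float, float]:
    """Recall for the same signal planted in a common drug (erenumab-like
    prevalence) and a rare one (fremanezumab-like), each against its own
    control group. Returns (recall_large_corpus, recall_small_corpus)."""
    base_config = config or SyntheticConfig.study_scale()
    recalls_large, recalls_small = [], []
    for i in range(n_runs):
        seed = derive_seed(base_seed, 4, i)
        cfg = replace(
            base_config,
            seed=seed,
            planted_signals=(
                ("erenumab", word, float(rate_ratio)),
                ("fremanezumab", word, float(rate_ratio)),
            ),
        )
        sim = simulate(cfg)
        res_large = drug_vs_group(sim, "erenumab", 3, 4, seed, test_config)
        res_small = drug_vs_group(sim, "fremanezumab", 4, 4, seed, test_config)
        recalls_large.append(score_recovery(res_large, {word}).recall)
        recalls_small.append(score_recovery(res_small, {word}).recall)
    return float(np.mean(recalls_large)), float(np.mean(recalls_small))
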