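#!/usr/bin/env python
"""Generate the study-scale synthetic post collection.

Draws a ~22.5k-post collection with the observed per-drug mention
prevalences and plants two adverse-event-like signals for the later
comparisons to find: "appetite" at 8x background rate inside topiramate
posts (a known topiramate side effect in the validation phase) and
"constipation" at 8x inside erenumab posts (the application-phase
finding). The full collection goes to scratch/ (it is large); a small
corpus summary lands in results/.
"""

import argparse
from pathlib import Path

from pharmakeyword.ingest import save_posts
from pharmakeyword.lexicon import build_corpora, default_lexicon
from pharmakeyword.pipeline import corpus_summary
from pharmakeyword.synthetic import SyntheticConfig, generate_posts

ROOT = Path(__file__).resolve().parent.parent

PLANTED = (
    ("topiramate", "appetite", 8.0),
    ("erenumab", "constipation", 8.0),
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "posts.jsonl")
    args = parser.parse_args()

    config = SyntheticConfig.study_scale(seed=args.seed, planted_signals=PLANTED)
    posts = generate_posts(config)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    save_posts(posts, args.out)
    print(f"wrote {len(posts)} posts to {args.out}")

    lexicon = default_lexicon()
    assignment = build_corpora(posts, lexicon, sorted(config.drug_prevalence))
    summary = corpus_summary(assignment, total_posts=len(posts), decimals=2)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "simulated_corpus_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"control pool: {len(assignment.control_pool)} posts")


if __name__ == "__main__":
    main()
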