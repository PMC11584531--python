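# pharmakeyword

Corpus-comparison keyword extraction for social-media pharmacovigilance.

Patient forums discuss drug side effects long before they surface in
spontaneous-report databases. Given a collection of forum posts, this
package assembles a *corpus* per drug (every post mentioning one of its
brand or generic names), builds a matched control pool, and flags words
whose frequency is statistically elevated in a drug's corpus relative
to a comparison corpus. The flagged keywords are candidates for
adverse-event signals — e.g. "appetite" for topiramate or
"constipation" for erenumab — to be adjudicated by a human reviewer or
an explicit highlight dictionary; the pipeline never auto-labels a word
as an adverse event. It is aimed at pharmacoepidemiologists and
informaticians who want a reproducible, seedable version of this
analysis, plus a synthetic corpus generator to measure its operating
characteristics (false-discovery behaviour, power, corpus-size effects)
before trusting it on real data.

## Method

For each word *q* in the union vocabulary of corpora *S* and *T*, a
one-tailed Welch (unequal-variance) two-sample *t*-test asks whether
*q* is more frequent in *S*:

```
t = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂)
```

with two choices of sampling unit:

* **token mode** (default): every token position is a Bernoulli trial;
  *n*ᵢ is the corpus token total, x̄ᵢ = countᵢ/nᵢ, and sᵢ² is the
  unbiased sample variance of the 0/1 indicator vector,
  x̄ᵢ(1 − x̄ᵢ)·nᵢ/(nᵢ − 1);
* **text mode**: every post is a sampling unit; the observation is the
  word's relative frequency within the post, robust to burstiness.

Words are *significant* when *t* > 1.73 (a configurable one-tailed
cutoff), ranked by the upper-tail *p*-value from the
Welch–Satterthwaite *t* distribution, and *retained* via the
Benjamini–Hochberg step-up rule (largest *k* with p₍ᵢ₎ ≤ i·q/m). Two BH
scopes are available: `significant_only` applies BH to the ranked list
of already-significant words (the historical two-stage procedure this
pipeline replicates — permissive, see `docs/methods.md`), and
`all_words` is the standard FDR-controlling variant used by the
validation experiments.

Text normalization: title and body are joined, lowercased, and split on
non-letter characters; tokens shorter than 3 characters are dropped.
Drug matching is whole-token, controls exclude every study drug and all
CGRP-class therapeutics, the control pool is split into k random groups
by a seeded generator, and posts shared by two compared drug corpora
are removed from both.

## Worked example

```python
>>> from pharmakeyword import welch_t
>>> welch_t(5, 100, 1, 200)   # count/total for corpus S vs corpus T
(2.0028743727144844, 0.02383151575981076)
```

A word seen 5 times in 100 tokens versus once in 200 tokens gives
t ≈ 2.00 (above the 1.73 cutoff) with one-tailed p ≈ 0.024.

End to end, on a synthetic ~22.5k-post collection with "appetite"
planted at 8× its background rate inside topiramate posts:

```python
from pharmakeyword import (SyntheticConfig, generate_posts, default_lexicon,
                           default_study_plan, run_study)

cfg = SyntheticConfig.study_scale(seed=17,
                                 planted_signals=(("topiramate", "appetite", 8.0),))
posts = generate_posts(cfg)
report = run_study(posts, default_lexicon(), default_study_plan(seed=17))
res = report.results["topiramate_vs_group2"]
print(len(res.table), len(res.significant_words), len(res.retained))
print(res.table.head(4)[["word", "count1", "count2", "t_stat"]])
```

prints `5008 66 66` — 5008 words tested, 66 crossing t > 1.73, all 66
surviving the two-stage BH — and the top of the ranked table:

```
      word  count1  count2    t_stat
  trokendi     485       0 22.084225
   topamax     479       0 21.946436
topiramate     436       0 20.933006
  appetite     429     180 18.026954
```

The three topiramate synonyms lead (they occur in every topiramate post
and never in controls) followed by the planted adverse-event word —
the same shape as real output, where drug names and forum vocabulary
dominate and side-effect terms appear among the retained keywords.

The same pipeline is available from the shell:

```bash
pharmakeyword simulate --preset study_scale --seed 17 --out posts.jsonl
pharmakeyword run --posts posts.jsonl --seed 17 --outdir out/
pharmakeyword compare --corpus-a a.jsonl --corpus-b b.jsonl --out cmp.tsv
pharmakeyword show-config
```

`run` writes one ranked TSV plus a JSON metadata sidecar per
comparison, a corpus summary, and a Markdown report; outputs are
byte-identical across reruns with the same inputs and seed.

## Analysis scripts

The `analysis/` drivers reproduce the study design end to end on
synthetic data and write small tables under `results/`:

1. `01_simulate_collection.py` — draw the study-scale collection with
   planted signals ("appetite" in topiramate posts, "constipation" in
   erenumab posts); summary of per-drug corpus sizes.
2. `02_run_study.py` — run the six-comparison plan (validation drugs
   head-to-head and vs control groups; the two CGRP monoclonals vs
   control groups and head-to-head); retained keywords per comparison.
3. `03_null_calibration.py` — repeated null comparisons (control group
   vs control group): how often anything is falsely retained.
4. `04_signal_recovery.py` — power curve over planted rate ratios and
   the large-vs-small corpus recall asymmetry.

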