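# Methods

## Pipeline

The analysis treats keyword discovery as a corpus-comparison problem.

1. **Ingest.** Posts (JSON-lines in the Pushshift submission schema, or
   generic CSV) are reduced to identifier, timestamp, title and body;
   all other fields, including usernames, are discarded. Title and body
   are joined with a single space and lowercased. Records without a
   timestamp are skipped and counted. The date filter is half-open,
   `start ≤ t < end`, so a ten-year window from one January 1st to the
   next contains no double-counted boundary day.
2. **Corpus assembly.** A drug's corpus is the set of posts containing
   any of its synonyms as a whole token. Matching tokens are maximal
   runs of letters and digits: `"topamax!"` matches the synonym
   `topamax`, but a fused dose such as `"topamax50"` stays one token
   and does not. There is no fuzzy matching and no negation handling
   ("never took topamax" counts as a mention). The control pool is
   every post mentioning no study drug and no CGRP-class therapeutic,
   split into k groups by assigning each post an independent uniform
   digit from a seeded generator (ids processed in sorted order, so the
   split depends only on pool content and seed). Posts present in both
   corpora of a drug-vs-drug comparison are removed from both sides;
   drug-vs-control comparisons need no removal because controls contain
   no drug mentions by construction.
3. **Tokenization.** Analysis tokens are maximal runs of letters —
   digits and symbols act as separators, so `"50mg"` yields `"mg"`
   rather than a fused pseudo-word — and tokens shorter than 3
   characters are dropped (length-3 words are kept; the threshold is
   configurable). Apostrophes separate, so `"didn't"` contributes
   `didn`. No stemming, stop-word removal or spelling correction:
   the test operates on raw surface forms.
4. **Per-word test.** For each word in the union vocabulary with total
   count ≥ `min_total_count`, a one-tailed Welch t-statistic measures
   excess frequency in corpus S over corpus T (details below).
5. **Retention.** Words with t above the threshold are ranked by
   ascending p-value and filtered by the Benjamini–Hochberg step-up
   rule. The ordered retained list is the comparison's keyword output.
   An optional highlight dictionary annotates retained words; the
   pipeline never labels a word as an adverse event on its own.

## The test statistic

Welch's unequal-variance two-sample t is used throughout:
t = (x̄₁ − x̄₂)/√(s₁²/n₁ + s₂²/n₂), with the Welch–Satterthwaite degrees
of freedom for the p-value (computed with `scipy.stats.t.sf`).

**Token mode** (default) treats each token position as a Bernoulli
trial for "is this token the word q". Then nᵢ is the corpus token
total, x̄ᵢ = countᵢ/nᵢ, and sᵢ² is the *unbiased* sample variance of
the 0/1 indicator vector, x̄ᵢ(1 − x̄ᵢ)·nᵢ/(nᵢ − 1). With this choice the
statistic is identical — to machine precision — to materializing the
indicator vectors and running a textbook Welch test on them, which the
test suite verifies against scipy on thousands of randomized cases.
The population-variance shortcut x̄(1 − x̄) differs by a factor
n/(n − 1); at corpus scale the two are indistinguishable, and the
unbiased form was chosen so that one exact oracle covers the
implementation. Degenerate cases: if both variances are zero the
statistic is 0 for equal means and ±∞ otherwise (p = 0.5, 0, 1); a
corpus with fewer than two sampling units has its variance taken as 0.

**Text mode** treats each post as the sampling unit and the word's
within-post relative frequency as the observation, with the unbiased
sample variance across posts and nᵢ = number of posts. Empty posts
contribute frequency 0. Text mode is the robust choice when words are
*bursty* — occurring in clumps within individual posts — which
violates the token-level independence assumption and inflates
token-mode significance. The synthetic generator's burstiness option
exists to demonstrate exactly this failure mode (see below). Token
mode is the default because the corpus-total notation (n as the word
total of each corpus) is the convention this pipeline replicates;
text mode is one configuration switch away.

## Significance threshold and BH scope

The significance rule is the literal cutoff **t > 1.73**, exposed as
`t_threshold`. For the large degrees of freedom of real corpora a
one-tailed 5% cutoff would be 1.645; 1.73 corresponds to roughly 19
df. The pipeline keeps the operative threshold as a configurable
constant rather than recomputing a critical value, because the
decision rule — not its derivation — is what defines the replicated
procedure; p-values are computed for ranking and BH only.

Two BH scopes are provided, and the distinction matters:

* `significant_only` (default) applies the step-up rule to the ranked
  list of *already significant* words, with m equal to that list's
  length. This replicates the historical two-stage procedure, but it
  does not control the false-discovery rate: under a global null the
  significant words are precisely those with small p-values, so their
  empirical quantiles sit near the BH thresholds and the rule
  frequently retains the entire significant list. This is visible in
  the analysis runs, where null-free drug-vs-drug comparisons retain
  hundreds of ordinary forum words.
* `all_words` applies BH over the full tested vocabulary and is the
  statistically standard variant; under the global null the retained
  list is then empty in at least a fraction 1 − q of runs. The
  calibration and power experiments use this scope, since "how often
  does the pipeline flag anything under the null" is only a meaningful
  question when the retention step actually controls errors.

Ties in p-value are broken by descending t, then lexicographic word
order, so output tables are deterministic. Summary percentages are
rounded half-up (`decimal.Decimal`), matching how printed values such
as "6.33%" arise from 1423/22467.

## Synthetic collections

The generator emulates the statistical structure the analysis assumes,
at the scale of a decade of a mid-sized patient forum:

* ~22,467 posts (the `study_scale` preset), timestamps evenly spaced
  over 2010–2019;
* a Zipf background vocabulary (default 5,000 words, exponent 1.1):
  rank-k probability ∝ k^(−1.1);
* negative-binomial post lengths (mean 60 filtered tokens, dispersion
  1.2 — heavily right-skewed, like forum posts: many short questions,
  a few long stories). The values are the package's choice of a
  realistic regime; nothing downstream is sensitive to them beyond
  total token counts;
* independent per-post drug mentions at prevalences 0.0179, 0.0633,
  0.0208 and 0.0032 for propranolol, topiramate, erenumab and
  fremanezumab — the observed extraction fractions (402, 1423, 468 and
  73 posts out of 22,467). One randomly chosen synonym of each
  mentioned drug is spliced into the token stream at a random position,
  so corpus assembly works on synthetic text exactly as on real text;
* planted signals: inside posts mentioning a given drug, a chosen
  word's per-token rate is multiplied by a rate ratio and the
  distribution renormalized. Planted words are placed at Zipf rank 150
  by default (a moderately common word, base rate ≈ 6×10⁻⁴ — the
  regime where detection is neither trivial nor hopeless);
* an optional burstiness mode draws each post's word distribution from
  a Dirichlet centred on the background (concentration × base
  probabilities), producing within-post clumping. It is off by
  default; the null model is otherwise exactly the iid sampling that
  token mode assumes.

The same seeded draw backs both the rendered title/body posts and the
token-level view used by the Monte Carlo experiments; a test verifies
that re-tokenizing the rendered posts reproduces the generated token
lists exactly, and generation is bit-reproducible for a fixed config.

What the generator does **not** emulate: topical structure, vocabulary
drift over time, comments, misspellings, multi-word symptom phrases,
or correlated drug mentions. Passing the synthetic experiments
therefore shows that the statistics behave as designed under the
model's assumptions — calibrated nulls, monotone power, corpus-size
effects — not that real forum text satisfies those assumptions. The
burstiness option exists precisely because real text does not.

## Validation experiments and problem sizes

The experiment module runs, at the `study_scale` scale:

* **Null calibration** (200 runs): control group 1 vs control group 2
  — identical generating distributions. Observed: the `all_words`
  retained list is empty in ≥ 99% of runs, and the pre-BH fraction of
  words with t > 1.73 averages ≈ 0.041 (nominal one-tailed ≈ 0.042).
* **Recovery** (100 runs): a word planted at 8× background in the
  6.33%-prevalence drug is retained in the drug-vs-control comparison
  with recall 1.0; over rate ratios 1/2/4/8 (50 paired seeds) mean
  recall rises 0 → ≈0.85 → 1 → 1, monotone.
* **Corpus-size asymmetry** (paired runs): the same rate-ratio-4 signal
  is recovered with recall ≈ 1 in the ~470-post corpus but ≈ 0 in the
  ~70-post corpus — the small-corpus regime in which a rarely
  discussed drug shows no keywords even when an adverse event is
  mentioned at an elevated rate.

Per-run seeds are derived from one base seed via `SeedSequence`, so
every experiment is reproducible end to end. The run counts above are
the package's standard operating points (they complete in a few
minutes on one CPU) and are parameters of every experiment function.

## Known limitations

* Unigrams only: multi-word expressions ("brain fog") fragment, and
  synonymous descriptions ("dizzy", "dizziness", "lightheaded") are
  tested separately, splitting their evidence. An optional pooling map
  (surface form → pooled key) is available in the study plan but off
  by default.
* The default retention scope reproduces a permissive two-stage
  procedure; its output lists are long and require downstream
  adjudication. Use `bh_scope="all_words"` for error-controlled lists.
* Drug matching is exact whole-token; misspellings beyond those listed
  in the lexicon are missed, and negated mentions count.
* Token mode assumes within-corpus token independence; bursty words
  can be over-flagged. Text mode trades this for lower power on short
  corpora.
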