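# Methods

This note records the modelling assumptions, default parameters, and design
choices behind `cognote`, in the spirit of a model-description appendix.

## Problem and unit of analysis

The unit is a *note section*: a contiguous excerpt of a clinical note,
labelled 1 when it documents signs of progressive cognitive decline
(concerns, symptoms, diagnoses, cognitive assessments, or cognition-directed
therapies) and 0 otherwise.  Non-progressive mentions — improvement,
transient medication effects, reversible post-event confusion, explicit
negations, and uncertain observations — are negatives by definition, and are
the interesting hard cases: they contain the same vocabulary as positives.

## Synthetic corpus generator

Real annotated EHR sections cannot be distributed, so all development and
testing runs on generated corpora that reproduce the statistical skeleton of
two reference collections:

| profile | n | positive rate | mean length (chars) | length range |
|---|---|---|---|---|
| development (keyword-enriched) | 4,949 | 29.4% | ≈850 | 26–9,323 |
| test (unfiltered) | 1,996 | 3.5% | ≈464 | 26–14,740 |

Choices and rationale:

* **Lengths** are drawn from a log-normal, rejection-truncated to the
  configured range.  Only a mean and a range are known for the reference
  data; a range an order of magnitude above the mean implies strong right
  skew, which the log-normal captures with two parameters.  `length_log_sd`
  defaults to 1.0; `length_log_mean` (6.28 / 5.68) was calibrated once so
  the *composed* text (built from whole sentences, so length lands within
  ±20% of the sampled target) realizes the target mean within a few percent.
* **Labels** are i.i.d. Bernoulli(positive_rate), so the realized rate obeys
  exact binomial concentration — the property the calibration tests check.
* **Composition**: sections are concatenations of clinically neutral filler
  sentences; positives additionally embed one or two cue phrases (from
  distinct evidence categories), and exactly
  `round(hard_negative_share × n_negatives)` negatives embed one
  hard-negative cue, categories dealt round-robin.  Cue phrases always
  contain an expert-lexicon keyword and fillers never do, which makes the
  keyword filter's behaviour on generated corpora exactly predictable:
  it retains 100% of positives and precisely the hard-negative share of
  negatives.  `hard_negative_share` defaults to 0.3.
* **Patients**: sections are dealt to synthetic patients with geometric
  sizes (mean 2.5 sections/patient for the development profile, matching
  4,949 sections over 1,969 patients; 1.7 for the test profile).
* **Annotation noise** is off by default (`label_flip_rate = 0`); the
  reference annotation process was high-agreement (Fleiss κ 0.83) and is
  not simulated.

What the generator does *not* emulate: realistic clinical language, topic
drift, section structure, longitudinal correlation within patients, or
ambiguous boundary cases.  Tests passing on synthetic corpora therefore
demonstrate the *machinery* (calibration, determinism, selection rules,
ensemble arithmetic, interval coverage) — not clinical performance.  Real
performance numbers require real annotated notes.

## Keyword lexicon and matching

The shipped lexicon carries four sources: the expert-curated screening terms
and the three model-derived lists (boosted trees, attention network, LLM).
Entries ending in `-` are stems matching any token prefix; all others match
whole tokens; multiword entries match contiguous token runs.  Tokenization
splits on every non-alphanumeric character and lowercases, because clinical
punctuation is noisy and the stems are word prefixes.  Terms without a
trailing hyphen (e.g. `alter`) default to whole-word matching; whether such
terms were intended as stems is unknowable from the published list, so the
behaviour is configurable per entry.  Character counts use Unicode code
points.

## Prompting and the scripted backend

Prompts have four blocks in fixed order: task description (always asking
for the judgment, the supporting keywords, and JSON output), optional
guidance, an optional five-shot examples block, and an optional paragraph of
error cautions.  Responses fall into three categories: effective and
parseable (JSON answering both questions), effective but not parseable
(both questions answered in free text), not effective.  The *effective
response rate* counts the first two categories by default (configurable),
since both answer the questions.  Sections whose response is not parseable
after one verbatim retry default to a negative prediction with a logged
flag — how such responses should enter the metrics is genuinely open, and
defaulting to the majority class with an audit trail is the conservative
choice.

The scripted backend is the deterministic test double for a hosted LLM.  It
recovers the target section from the prompt, computes a base label from
expert-keyword presence (downgraded to 0 when a hard-negative cue and no
positive cue is present — emulating contextual understanding), then applies
seeded flips: a uniform `flip_rate_overall` plus per-category flips on
sections carrying a given hard-negative cue category.  This gives each
scripted "model" a distinct, reproducible error profile.  Error-analysis
cautions that name a category suppress that category's flips, reproducing
the mechanism by which error-analysis-based instructions help a real LLM.
Format-breaking and refusal behaviours are available at configurable rates.
All draws are keyed by (seed, section id), so responses are byte-stable.

The manual template-tuning loop of a human prompt engineer is represented by
its outcome: a registry of templates ranked by effective response rate, then
selection accuracy ((TP+TN)/N).  Live-API backends can be plugged in via the
two-method backend contract but are intentionally outside the test suite.

## Few-shot selection

k defaults to 5 (token-budget convention).  The default embedding space is
L2-normalised TF-IDF unigrams fitted on the example pool: deterministic,
local, and sufficient for lexical-similarity geometry.  k-means uses 10
seeded restarts, a 300-iteration cap, Euclidean distance, and returns per
cluster the pool member nearest the centroid (ties and collisions resolve to
the lowest pool index, with a warning on degenerate clusterings).  kNN uses
cosine similarity, recomputed per query, ties to the lower index, zero
vectors defined as similarity 0 with a warning, and never returns a pool
member sharing the query's id.

## Baselines

*Boosted trees.*  TF-IDF unigram features with document-frequency floor 2
(an era-typical boosted-tree text pipeline that feeds the gain-based
interpretation naturally), grid {50, 200} trees × depth {3, 6} × learning
rate {0.1, 0.3}, seeded stratified 5-fold CV, mean F1 as the selection
metric, first maximiser kept on ties, winner refit on all data.  Per-feature
total split gain is recorded for interpretation.

*Attention network.*  Token embedding (32) → same-padded 1-D convolution
(64 channels, kernel 3, ReLU) → bidirectional LSTM (32 per direction,
masked state carry so scores are independent of batch padding) → additive
attention pooling (softmax over valid positions) → sigmoid.  Implemented in
NumPy with explicit backprop and Adam (lr 0.01, batch 32, 15 epochs by
default; 512-token truncation).  The sizes are deliberately small for
single-core CPU training; the architecture was verified by numerical
gradient checking and by convergence on separable fixtures.  Training is
fully deterministic given (corpus, config, seed).

Scores are thresholded at 0.5 with a *strict* inequality (a score of
exactly 0.5 is negative); the cutoff convention leaves the tie unspecified,
so the tie rule is declared here.

## Ensemble

Majority vote over an odd number (≥ 3) of aligned prediction sets; even
counts are rejected rather than tie-broken because no tie rule is defined
for this task.  The ensemble errs exactly where ≥ 2 inputs err; with three
conditionally independent error processes at rate e its error rate is
3e²(1−e) + e³.

## Evaluation

Percentile bootstrap (B = 1,000 by default) over section resamples; BCa was
not used because nothing more than "bootstrap resampling" is specified and
the percentile method is the simplest member of that family.  Replicates on
which a metric is undefined (zero denominator) are dropped for that metric
and counted.  Resampling by *patient* is available behind a flag, since
section-level resampling ignores within-patient correlation.  The paired
comparison applies the same resample indices to both models and t-tests the
replicate-wise differences; all-zero differences report p = 1 by convention.
Zero-denominator point metrics are reported as undefined, never coerced to
zero.

## Interpretation

The selection rule is strictly-greater-than mean + 2 × sample SD (ddof = 1);
the SD estimator is not specified anywhere authoritative, so the sample SD
is declared.  Channels: (i) LLM — case-folded, whitespace-collapsed
citation counts across parseable verdicts (multiword keywords intact);
(ii) attention — the within-section mean+2SD rule, aggregated across
sections by counting the sections that selected each token, reported at a
count floor of 2 (the cross-section aggregation behind published keyword
lists is unstated; counting selections is the simplest frequency-based
choice); (iii) boosted trees — mean+2SD over total split gain.  Expert
lexicon rows are always included, with no importance value.

## Error analysis

Pairwise overlap counts are stored *inclusive* of the triple overlap: with
the published counts (31, 23, 22; 4, 3, 8; 2) inclusion–exclusion yields the
published union of 63 only under the inclusive reading, so it is adopted;
the exclusive reading is arithmetically inconsistent with that union.
Percentages round half-up to one decimal.  The Venn figure is an annotated
schematic (areas not proportional).  The qualitative clinical
categorization of errors is out of scope; only the quantitative accounting
is implemented.

## Pipeline and problem sizes

`run_experiment` executes: generate → filter accounting → backend/template
selection (effective response rate on a 10-section probe, then accuracy on
a 200-section selection split) → five-shot strategy comparison →
error-instruction augmentation (the final prompting strategy is the
accuracy argmax) → baseline training on the development analog →
classification of the test analog by all three models → majority vote →
bootstrap metrics and paired tests → keyword report → overlap report, all
under one run directory with a manifest (config hash, seeds, version) that
contains no timestamps, so identical configs reproduce identical artefacts.
The development analog is generated directly at its published keyword-
enriched positive rate (29.4%); the filter stage reports retention
accounting rather than defining the training set, because re-deriving the
enriched corpus from a raw pool would require simulating the much larger
unscreened note stream for no additional test value.

The test suite and the acceptance script run the heavy statistical checks at
the reference sizes (n = 10,000 ensemble simulation; n = 4,949 and 1,996
corpora; 300–500 coverage replicates at n = 500 with B = 1,000) and the
learnability checks on a 500-section separable fixture; the end-to-end
pipeline test uses a few hundred sections per stage, which exercises every
code path at desk scale.

## Known limitations

* Synthetic text is templated; lexical diversity is far below real notes,
  so absolute classifier performance on these corpora says nothing about
  clinical accuracy.
* The scripted backend's error profiles are injected, not emergent; they
  validate the ensemble and evaluation machinery, not LLM behaviour.
* Model objects are exchanged in memory and predictions as CSV; trained
  models are not serialized to disk.
* Patient-level train/test disjointness is available but off by default,
  mirroring the section-level convention of the reference design.
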