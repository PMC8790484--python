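# Methods

This note documents the models, procedures, parameter defaults, and design
choices implemented in `vflda`.

## Transcript scoring

A transcript is an ordered list of (word, onset) pairs within a 60-s trial;
onsets must be strictly increasing. Words are normalized before any lookup:
lowercase, NFC unicode, punctuation stripped, internal whitespace joined
with an underscore ("rose bed" → `rose_bed`). Labels are assigned by a
single left-to-right pass:

* a repetition of **any** previously produced word — correct or not, at any
  lag, including immediate repetition — is a **perseveration**, pointing back
  to the word's first occurrence;
* a first production inside the category lexicon is **correct**;
* a first production outside the lexicon that has a topic profile is an
  **intrusion**;
* an utterance with no profile at all is a **non-word**. Non-words keep a
  distinct internal label but are folded into intrusion counts in every
  aggregate (totals, phase summaries, interval modes, within-cluster
  denominators), since unknown utterances are conventionally tallied with
  intrusions.

Multiword responses are looked up as the joined token first; failing that,
the profile is the normalized mean of the constituent tokens' profiles;
failing that, no profile.

Label counts are conserved: correct + perseverations + intrusions
(+ non-words) = number of responses, always.

## Topic model and word profiles

The topic model is standard LDA: documents mix K latent topics drawn from a
Dirichlet(α) prior; each topic is a distribution over the vocabulary.
Fitting uses batch variational inference (scikit-learn) with a fixed random
seed and an iteration/tolerance stopping rule (defaults: 100 iterations,
perplexity tolerance 1e-3, topic–word prior 0.1). Runs with the same seed
and corpus are bit-identical.

**Word profiles.** The per-word topic probability is the posterior
p(k | w) ∝ φ_k(w) · p(k), normalized to sum to 1. The prior p(k) is the
corpus-level topic prevalence, estimated as the length-weighted mean of the
document–topic posteriors — i.e. the expected share of corpus tokens carried
by each topic. Words absent from the fitted vocabulary have **no profile**;
they are flagged, never imputed.

**Model selection.** The canonical grid is K = 3..15 crossed with
α ∈ {0.2, 0.3, 0.4, 0.5, 1} (65 candidates). Leave-one-out cross-validation
over tens of thousands of documents is computationally disproportionate, so
selection uses k-fold (default 5) held-out **document completion**: the
model is fit on the training folds; for each held-out document the topic
mixture is inferred from the even-index half of its tokens (fixed-point EM
with φ frozen, 50 iterations) and the log-likelihood of the odd-index half
is evaluated under θ·φ. The score is the per-held-out-token log-likelihood;
ties break toward smaller K, then smaller α (parsimony). The deviation from
true LOOCV is recorded in the run metadata.

## Cluster identification

With a K-topic model the cluster criterion is c = (1/K) × 0.5 (0.0357 for
K = 14). Adjacent responses i, i+1 are *linked* iff some topic k satisfies
p(k | w_i) > c **and** p(k | w_{i+1}) > c (strictly greater). Maximal runs
of linked pairs with ≥ 2 responses form cluster spans. Error responses
participate in clusters; responses with no profile can never link.

Each adjacent pair carries its set of shared above-threshold topics. A
**transposition** is logged at the left response of a pair whose shared set
is disjoint from the previous pair's while the run stays linked — this
reproduces deterministically the canonical example monkey(3), gorilla(3),
chimpanzee(3, 9), kangaroo(8, 9): one 4-word cluster with a 3 → 9
transposition at "chimpanzee".

Raising c can only remove linked pairs, never add them (monotonicity,
property-tested).

**Summed topic probabilities** over a response subset add the profiles
componentwise; because each profile sums to 1, the grand total equals the
number of profiled responses (unprofiled responses are skipped and counted).
Error–topic association is the Pearson correlation across the K paired
components of an error subset's topic sum and a reference subset's topic
sum; zero variance yields an explicit undefined signal rather than a number.

## Time course

Phases are half-open 15-s bins [0, 15), [15, 30), [30, 45), [45, 60) on the
response **onset**; the boundary convention is a package choice (the field
does not standardize it) and is deterministic with no double counting.
Interval endpoints are onset-to-onset; articulation duration is ignored.
Three interval modes: (a) same-word — consecutive occurrence pairs of each
repeated word (1st→2nd, 2nd→3rd, never 1st→3rd); (b) intrusion→intrusion;
(c) any error→any error, each between consecutive qualifying events in
onset order. A transcript with fewer than two qualifying events contributes
no intervals. Words-amid-errors counts correct responses with onsets
strictly inside an interval.

## Group statistics

* **One-way ANOVA** with partial eta squared
  η_p² = SS_effect / (SS_effect + SS_error); post hocs are pairwise t-tests
  on the pooled within-group error (df = N − k) with Holm step-down
  adjustment.
* **Mixed (split-plot) ANOVA**, group (between) × phase (within): the group
  effect is tested against subjects-within-groups, phase and the interaction
  against the subject × phase residual; no sphericity correction is applied.
  For 66 subjects in 3 groups and 4 phases the dfs are (2, 63), (3, 189),
  (6, 189). The decomposition is authored here and cross-checked in the test
  suite against pingouin's independent implementation.
* **Chi-square** is the uncorrected Pearson statistic (no Yates correction),
  df = (r−1)(c−1), with Cohen's w = √(χ²/N) and Haberman adjusted
  standardized residuals (O−E)/√(E(1−row/N)(1−col/N)); cells with
  |z| > 1.96 are flagged (two-tailed 5%).
* **Median split**: within each group, total errors (perseverations +
  intrusions) are compared to the group median (even-sized samples use the
  midpoint of the two central order statistics); totals **greater than or
  equal to** the median join the high-error subgroup. When all totals are 0
  the rule degenerately assigns everyone to the high-error subgroup; this is
  a documented artifact of the ≥ convention.

## Synthetic data

The corpus generator draws documents from the LDA generative process:
θ_d ~ Dirichlet(α_true · 1_K), document length ~ Poisson(mean, ≥ 1), each
token draws a topic from θ_d and a word from the planted topic row. A
planted topic row puts weight 1 on its own words, 0.5 on shared words, and a
small leak β_true (default 0.1; 0.005–0.02 in separability tests) on foreign
words, then normalizes. The true matrices are returned for recovery tests.

The cohort generator emulates 60-s animal-fluency trials over six planted
subcategories (farm, sea, birds, safari, forest, pets; 12 words each) with
related out-of-category words attached to each subcategory for intrusions:

* **Correct responses**: inhomogeneous Poisson with per-phase rates, onsets
  uniform within each 15-s phase, then a forward jitter enforcing a minimal
  0.3-s inter-onset gap (events pushed past 60 s are dropped). Words walk
  across subcategories — stay with probability `topic_coherence` (default
  0.6), otherwise switch — and never repeat.
* **Intrusions**: per-phase Poisson counts; each intrusion attaches to the
  temporally nearest correct response's subcategory with probability 0.56
  (so roughly half of intrusions fall inside clusters), otherwise to a
  random subcategory, and draws a related non-animal word without
  replacement.
* **Perseverations**: per-phase Poisson counts; the repeated word is chosen
  among earlier responses with weights proportional to the exponential lag
  density exp(−lag/`perseveration_lag_mean`). Placement by phase rates is
  exact; the lag preference is soft. This resolves the tension between
  controlling the phase distribution (needed for time-course recovery
  tests) and the long-lag character of real perseverations.

Default group profiles encode the three study-like populations — correct
totals 20.6 / 18.8 / 12.9 (young / older / AD-like), intrusion totals
0 / 0.09 / 0.95 concentrated in phase 1 for the AD-like profile,
perseveration totals 0.46 / 0.87 / 1.26 peaking in phase 4, lag mean 22 s —
with monotone-declining per-phase production.

**What the generator does not emulate**: articulation and pause structure
beyond onsets, morphology or real lexical frequency effects, semantic
distance within a subcategory, and response-time dependence on retrieval
difficulty. Passing tests therefore demonstrate the correctness of the
scoring, clustering, time-course, and statistical machinery under the
declared generative assumptions — not clinical validity on real recordings.
The distributional form of production decline (Poisson per phase) is a
stand-in; the field reports only that production declines.

## Numerical choices and degenerate inputs

* Comparisons against the cluster criterion are strictly greater.
* Profile normalization asserts Σ = 1 within 1e-8 in types and tests.
* Undefined quantities (correlation of a constant vector, error shares with
  zero denominators, chi-square on a table with a zero marginal) return
  explicit signals (`None`) or raise with a named reason — never NaN leaking
  silently.
* All randomness flows from a single root seed through `SeedSequence`-derived
  stage/subject sub-seeds; two runs with the same configuration are
  byte-identical, which the test suite asserts on the pipeline's TSVs.

## Problem sizes

The test and example corpora use 100–500 documents of ~25–40 tokens over
vocabularies of 18–96 words, cohorts of up to 200 simulated subjects, and
model-selection grids of up to five candidate K values with 2–3 folds. These
sizes give stable recoveries (topic-matching cosines > 0.9, Monte-Carlo
phase-share errors < 0.1) while keeping a full run fast on a single CPU; the
full 65-model grid is exposed (`STUDY_K_VALUES`, `STUDY_ALPHA_VALUES`) for
larger corpora.
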