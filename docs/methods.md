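# Methods

## Problem and data model

The pipeline targets transcripts of wizard-of-oz clinical interviews: an
ordered list of timed turns (start time, stop time, speaker, utterance)
between a virtual interviewer and a participant, plus a per-participant
PHQ-8 table. The binary depression label follows the printed convention of
the label files this mirrors — `PHQ8_Score > 10 ⇒ PHQ8_Binary = 1` — with
the threshold configurable (`read_labels(threshold=9)` gives the common
`score ≥ 10` convention). Gender is carried through the label table but
never enters any model. Sessions without a single interviewer turn are
structurally broken for this feature set (most features hinge on the bot's
questions) and are excluded *before* splitting; a 188-session corpus with
3 broken sessions therefore retains 185 and splits deterministically into
148 train / 37 test at `train_fraction = 0.8` (train size is
`round(0.8 × 185)`; the assignment is a seeded uniform permutation).

## Cleaning

Cleaning removes annotation spans first (square/angle-bracketed and
parenthesised spans — content that was never spoken), then deletes basic
punctuation characters (`, . [ ]` plus a few more; apostrophes are kept so
contractions stay single words), lowercases, and collapses whitespace. The
operation is idempotent and never lengthens the text. Stop-word removal
exists as an opt-in flag but is off: filler-word frequency is itself a
feature, and removing stop words degraded classification when it was tried
on real interview data.

## Feature bank

"Comment" means one participant turn. The 30 features per session are:

* **19 answer-sentiment features.** A canonical pool of 19 questions; for
  each, the lexicon polarity of the concatenated participant turns between
  the bot turn that asked it (containment match of the cleaned question in
  the cleaned bot utterance; first match in pool order) and the next bot
  turn. A question that is absent — or asked but never answered — scores
  exactly 0, one consistent imputation rule. Only nine pool questions are
  attested in published top-feature tables; the other ten are synthetic
  placeholders, clearly marked in the source, so the pool reaches its 19
  slots. The pool is configurable.
* **avg_sentiment** — polarity of all participant speech pooled as one
  text (a per-comment-mean variant is switchable).
* **avg_response_time** — mean over bot→participant adjacencies of
  (participant start − preceding bot stop), negatives clamped to 0.
  Seconds.
* **speech_speed** — unweighted mean over participant turns of
  token count / duration, zero-duration or empty comments skipped.
  Words/second.
* **avg_unique_frequency, avg_sw_frequency, fp_avg, avg_nouns, avg_verbs,
  adj_freq, avg_adv** — unweighted means of per-comment ratios
  (count satisfying the predicate / comment length). Unweighted per-comment
  means (not pooled ratios) make the features invariant to permuting or
  duplicating the comment list.
* **avg_characters** — per comment, sum of token lengths / token count,
  averaged; whitespace is not counted, so this is a per-word length.

The sentiment scorer and POS tagger are injectable contracts. The defaults
are deterministic: a small graded polarity lexicon (entries in [−1, 1],
score = mean polarity over matched tokens, 0 when nothing matches) and a
dictionary tagger over a closed vocabulary. A production engine (e.g. a
trained polarity model or statistical tagger) can be passed through
`FeatureSpec(sentiment_scorer=…, tagger=…)` without touching the pipeline.

## Search and selection

Wrapper feature selection: all C(|pool|, k) subsets of an ordered feature
pool are crossed with the Cartesian hyperparameter grid of each estimator
family, every candidate is fit on the training rows restricted to its
subset and scored on the held-out rows, and nothing about the test side
ever feeds back into training. Defaults mirror the published experiment
geometry — pool of 17 (nine attested questions + eight global features;
the exact published membership is not recorded, so the pool is
config-driven), random forest with fixed parameters at k = 5 (6,188
models), XGBoost with n_estimators ∈ {100, 300, 500} at k = 4 (7,140),
SVM with gamma ∈ {1, 0.1, 0.01, 0.001} × C ∈ {1, 10, 100, 1000} ×
kernel ∈ {rbf, linear} at k = 4 (76,160). Fixed parameters follow the
published settings (XGBoost eval_metric=auc, learning_rate=0.01,
max_depth=12; the random forest's non-default max depth is not printed and
mirrors the XGBoost value, config-exposed). Each adapter receives the
spec's seed as its random state, so searches are bit-reproducible. A
failing candidate is recorded with its error and skipped by selection.
There is no cross-validation: evaluation uses the single fixed split, as
the original experiment did.

Selection ranks candidates by accuracy **subject to** the minority-class
F1 (the class with smaller test support) strictly exceeding a floor,
default 0 — a model that never identifies a depressed participant is
excluded regardless of accuracy. Ties break by minority F1, then fewer
features, then lexicographic subset, giving a total order. If no candidate
survives, the unconstrained ranking is returned with an explicit flag.
Metrics are computed from confusion counts with exact arithmetic
(accuracy = support-weighted mean recall identically); macro averages are
unweighted class means, weighted averages support-weighted, and the
2-decimal rounding in rendered tables is display-only.

## Synthetic corpus generator

The generator emulates the *statistical shape* of the restricted corpus,
not its language. Defaults are the study conditions: 188 sessions, 56
depressed, 3 structurally broken sessions, a 19-question pool with each
question present in a session with probability 0.85 (so no question is in
every session), and annotation markers injected into utterances at rate
0.15.

Each subject draws four latent parameters around class means:
speech rate (base 2.0 words/s, SD 0.2), mean response latency (base 1.0 s,
SD 0.5), negative-word rate (base 0.05, SD 0.04) and first-person rate
(base 0.10, SD 0.03). Depressed subjects are shifted by the configured
effect sizes — defaults −0.4 words/s, +1.0 s, +0.08 and +0.06
respectively, i.e. 2 between-subject SDs on the timing channels, the
regime the recovery checks target; `EffectSizes.scaled(c)` scales all four
for calibration experiments, and zero effects give exchangeable classes.
Utterance words are drawn from a closed vocabulary partitioned into
sentiment-bearing, first-person, filler and neutral (noun/verb/adjective/
adverb) words, making every feature analytically recountable from the
recorded per-session plan. Timing is constructive: participant turn
duration = word count / subject speech rate, and bot→participant gaps are
log-normal with the subject's mean latency (σ = 0.35), so speech_speed and
avg_response_time recover their planted values by design. Valid sessions
strictly alternate bot/participant turns with non-overlapping, increasing
times; broken sessions are participant monologues. PHQ-8 scores are drawn
uniformly in 11–24 (depressed) or 0–10 (controls), consistent with the
`> 10` rule.

Randomness: one global stream keyed by the seed assigns classes and broken
sessions; each session (and its label score) uses an independent substream
derived from the session index, so generation is order-independent and a
fixed config writes byte-identical corpora.

What the generator does *not* emulate: natural-language semantics and
syntax, topic structure, speaker disfluency patterns beyond a flat filler
rate, audio/video modalities, and any correlation between answer content
and the specific question asked. Passing recovery tests therefore shows
the pipeline's machinery is correct and sensitive at the planted effect
sizes; it says nothing about how strongly real depressed speech expresses
these signals.

## Numerical and testing choices

* Transcript times are written with full precision (`repr`) and feature
  CSVs with `%.17g` / round-trip parsing, so disk round-trips are exact.
* Ties in turn start times keep file order (stable sort).
* F1 is defined as 0 when precision + recall = 0; metrics of an empty
  class are 0, logged, never NaN.
* Desk-scale problem sizes: calibration and recovery suites use corpora of
  24–200 sessions and pools of 2–6 features, sizes at which the planted
  effects dominate sampling noise while the full suite stays fast.
  Signal recovery is judged over 20 seeds (selected model must beat the
  majority baseline in ≥ 18); the zero-effect control uses a per-seed
  one-sided binomial test of the selected model's correct count at the
  majority prevalence (α = 0.05), because max-over-candidates selection on
  a ~22-sample test set legitimately exceeds the baseline by one or two
  samples under the null.
* The null-effect calibration (100 replicates, rank test at α = 0.01)
  bounds false rejections at 5, the binomial-tolerant reading of a 1%
  level.

## Known limitations

Real transcripts vary in dialect (speaker names, annotation style); the
reader exposes a speaker-alias table and marker patterns but has only been
exercised on the dialect the generator writes. The default lexicon and
tagger are deliberately tiny; realistic scoring requires injecting
production engines. Selection on the single fixed test split is faithful
to the original experiment but optimistically biased — a development set
option is the natural extension, deliberately not enabled by default.
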