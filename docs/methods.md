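# Methods

This note documents the models and procedures implemented in `engagekit`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Engagement stratification

Engagement is measured per user per calendar year (Jan 1 – Dec 31) with
three counts:

- **threads initiated** — threads whose earliest-timestamp message (ties
  broken by message id) has this sender;
- **posts** — all messages sent;
- **replies attracted** — messages addressed to this user via
  `recipient_id`, plus recipient-less messages posted into a thread this
  user rooted; self-replies never count, and a reply is credited to the
  year it was posted.

Reply attribution needed a rule the data model does not dictate: explicit
recipient wins, thread-root attribution is the fallback. This matches how
threaded forums render replies (a recipient-less reply is visually a
response to the thread).

Top-*k* selection per metric per year is deterministic: rank by the
metric, break ties by higher post count then lexicographic user id, and
collapse exact duplicate profiles, so selection is invariant to input
order. Years with fewer than *k* active users contribute what they have,
with a warning. With k = 3 and a 16-year window this yields
3 × 3 × 16 = 144 assignment slots; the same user may hold several slots,
so the distinct-user count is reported alongside.

All reported shares go through one rounding rule,
`engagement.proportion`: round-half-up at the requested number of
decimals (decimal arithmetic, not float banker's rounding), which is what
published percentage/ratio pairs assume.

## Abstinence status

Quit duration is binned with fixed constants — 1 month := 30.44 days,
1 year := 365.25 days — into half-open intervals [lower, upper):
<3 months, 3–6 months, 6 months–1 year, 1–2 years, >2 years, plus
*active smoker* (explicit flag only) and *unknown*. Fixed constants make
the bins deterministic and the mapping monotone in days.

Status per (user, year) is assessed at a December 31 anchor. Event-log
quit dates take precedence: days = anchor − latest quit date on or before
the anchor. Without a usable log, the package parses the community's
quit-duration signatures ("`////13 days, 23 hours, 47 minutes and 51
seconds smoke free`", tolerant of decorations and partial forms; only
whole days count, sub-day components never round up). Each signature is a
time-stamped observation of elapsed smoke-free time, so it is
extrapolated to the anchor (parsed days + days between the message and
the anchor) before taking the maximum across the year's messages and
binning. Anchoring both evidence sources at the same date is what makes
them comparable: binning raw signature days would systematically
understate users whose quit anniversary falls between their last post and
year-end (about one in ten synthetic user-years at the default
conditions). When several signatures within a year conflict, the maximum
estimate wins; this is a package convention, not a claim about how manual
review resolved such conflicts.

The active-smoker category cannot be inferred from logs or signatures —
it requires a self-report field the message schema does not carry — so
`status_per_user_year` never emits it; it is reachable only through
`bin_abstinence`'s explicit flag. Users with no quit evidence are
*unknown*.

## Embeddings

Background term vectors come from skip-gram with negative sampling,
implemented in numpy inside the package: minibatch SGD (batch 2048) over
(center, context) pairs with dynamic context windows (radius uniform in
1..window), frequent-word subsampling (word2vec keep rule, threshold
1e-3), negatives drawn from the unigram distribution raised to 0.75, and
a linearly decaying learning rate from 0.025. Defaults follow word2vec
conventions: window 5, 5 negatives, 5 epochs, minimum frequency 5.
Dimension defaults to 500 (the classic choice for billion-word
corpora); the bundled fixture and the test suite use 50, which is ample
for a vocabulary of a few hundred terms. Training is single-threaded and
fully deterministic given the seed; duplicate indices inside a minibatch
are scatter-added, a standard minibatch variant of word2vec's
asynchronous updates.

The superposition cycle has three stages. Stage-1 message vectors sum the
background vectors of a message's in-vocabulary tokens *with
multiplicity*; corpus term vectors sum the stage-1 vectors of the
messages containing the term *by presence* (the phrase "each message in
which a term occurred" is presence semantics); stage-2 message vectors
sum corpus term vectors with multiplicity. Every stage unit-normalizes
its output. Normalization is a deliberate addition: without it, vector
magnitude tracks message length and term frequency and swamps
downstream classifiers; with it, superposition remains order-invariant
and additive up to the final scaling. Out-of-vocabulary tokens are
skipped silently at stage 1 but *included* at the term stage — that
asymmetry is the neologism-transfer mechanism by which community
coinages acquire meaningful vectors from their forum co-occurrence
contexts. Messages with no usable token get a zero vector, are flagged,
and are exempt from the unit-norm invariant; flagged messages receive no
theme labels. Term contributions are unweighted (no frequency damping);
one term↔message cycle is performed, and stage-2 message vectors use
corpus term vectors only.

Vector stores persist as word2vec-style text (`count dim` header, one
`token v1 … vd` line each) plus a JSON sidecar carrying provenance,
config and the flagged-id list.

## Classification

Each retained theme gets an independent binary classifier over stage-2
vectors. The event model is Gaussian naïve Bayes — the natural choice for
continuous embedding components — with a discretized (quantile-binned
categorical) alternative available as a config choice. Decision
threshold is 0.5 on the posterior.

Cross-validation is stratified 10-fold with a recorded seed; samples are
sorted by message id before folding so the report is invariant to
annotation order. Metrics are pooled (micro): held-out predictions from
all folds form one confusion matrix from which precision, recall and F
are computed, making every reported triple exactly reconstructable from
the stored matrix. Per-theme macro averages across themes are reported
alongside where a single summary triple is needed. When the minority
class has fewer members than folds, the fold count drops to that size
(never below 2), with a warning.

Themes with fewer than `min_positives` positive annotations are dropped
before training. The default floor is 30 — enough positives to stratify
ten folds meaningfully — and it is configurable; the filter's report
lists retained and dropped themes with counts.

Cohen's kappa is implemented closed-form ((p_o − p_e)/(1 − p_e) from the
raters' marginals) and is used both for system–rater and coder–coder
agreement; the test suite cross-checks it against an independent
implementation.

## Sentiment

Score = (positive-lexicon hits − negative-lexicon hits) / token count,
in [−1, 1]; direction is the sign, with 0 → neutral. This is the
simplest faithful dictionary ratio score; the lexicon is pluggable (two
plain word-list files), and a small general-purpose list ships with the
package. No negation or valence-shifter handling is attempted, so scores
on real text are lexicon-dependent; the recovery tests rely on injected
sentiment with a known mixture, not on lexicon completeness. Swapping
the lexicon sides negates every score exactly, and appending
lexicon-free text shrinks a score toward zero without crossing it —
both properties are tested.

## Synthetic data: what it emulates, and what passing tests show

The generator plants explicit per-theme token sets (12 synthetic tokens
per theme) rather than modeling free language: ground truth is exact and
recovery tests are sharp, at the cost of linguistic realism. Default
study conditions:

- 50 users over 2 years, archetype mix 10/10/10/70%
  (initiator/attractor/poster/background), giving ≈3,500 messages;
  a 30-user, 16-year variant exercises the 144-slot selection.
- Archetype rates: initiators ≈42 threads/user/year (posts 70/yr, 60%
  initiation), attractors attract replies at 8× weight (posts 50/yr),
  posters 150 posts/yr, background users 12/yr. Each post either opens a
  thread (per the sender's initiation propensity) or replies to an
  earlier same-year thread chosen proportionally to the root author's
  attraction weight, addressing the root author with probability 0.7.
- 8 rich themes with archetype-specific probabilities (0.2–0.74, echoing
  the magnitudes the framework is meant to detect) and 8 sparse themes
  at 1.5% each, so the default 200-message annotation subset retains
  exactly the rich half at the default floor of 30.
- One neologism per rich theme, present in 15% of that theme's messages
  and never in the background corpus.
- Sentiment injected at 70/20/10 positive/negative/neutral via two
  lexicon words per non-neutral message.
- Quit trajectories: per-archetype veteran/recent/never-quit mixes
  (attractors mostly recent quitters, initiators mostly veterans);
  57.6% of quitting users have event logs, the rest are recoverable only
  through signatures, which appear in 90% of a quitter's messages.
- Background corpus: 5,000 documents ≈200k tokens; each document draws
  one theme (60% theme tokens, 40% shared filler with Zipf exponent 1.1),
  which plants within-theme co-occurrence for the SGNS model.
- Message length: theme tokens (3–6 per true theme) plus Poisson(10)
  filler — short, terse messages.

Everything is deterministic under the seed; corpus and ground-truth files
are referentially complete.

Passing recovery tests on these conditions demonstrates that the
pipeline's machinery is correct and well-calibrated when content signals
exist (archetype slots recovered ≥90%, rich-theme macro-F1 ≥0.8 with a
permutation null at chance, sentiment mixture within ±5 points,
corpus-wide theme prevalence tracking truth within about ±5 points,
abstinence status ≥95%). It does **not** show that real forum text is
this separable: real messages mix themes without dedicated vocabulary,
real lexicons mislabel sarcasm and negation, and real engagement metrics
are heavier-tailed. Absolute performance numbers on real corpora will be
lower; the synthetic results validate implementation, not field
difficulty.

## Numerical and operational choices

- Problem sizes: the default fixture (≈3.5k messages, 200k background
  tokens, dimension 50) runs the full pipeline in about a minute on one
  CPU; the test suite and the acceptance script both use it end to end.
- Sparse linear algebra (scipy CSR count/presence matrices) implements
  the superposition stages; brute-force loop oracles in the tests pin
  the semantics (multiplicity vs presence, normalization, flagging).
- Tie-breaks are deterministic everywhere (timestamp then id for thread
  roots; metric, posts, id for selection; sorted ids for folding).
- The pipeline manifest records config hash, seeds and stage timings;
  embedding stores are cached by input/config hash, so re-running with
  changed reporting parameters skips retraining, and a re-run with the
  same config reproduces outputs byte-for-byte.

## Known limitations

- Active smokers are indistinguishable from silent users without a
  self-report field.
- The bundled lexicon is small and general-purpose; absolute sentiment
  shares on real text depend on the dictionary used.
- Naïve Bayes assumes conditionally independent vector components, which
  embedding dimensions violate in principle; it remains the reference
  classifier here, with the feature pipeline doing the heavy lifting.
- The SGNS trainer targets small-to-medium corpora (single-threaded,
  dense numpy); it is not a tool for billion-word training runs.
- Engagement metrics are count-based only; no network/centrality
  analysis is attempted.
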