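# Methods

This note documents the models, the defaults and the numerical choices
behind `trendmine`, and what the synthetic benchmarks do and do not
establish.

## Corpus model and filtering

A document is an id, a UTC timestamp, a text and an optional language
tag. All filters are record-local predicates (keyword, window,
language), so their composition is order-insensitive; deduplication is
applied last. Design choices where the procedure was open:

- **Keyword matching** is lowercase substring matching — phrases match
  as contiguous substrings, hashtags literally including `#`. This
  deliberately catches inflected and hashtag-embedded forms
  (`PfizerBioNTech` matches `pfizer`) without a tokenizer dependency.
- **Deduplication** is exact matching after a normal form: a leading
  `RT @handle:` marker is stripped, whitespace collapsed, text
  casefolded. The earliest copy (ties: smallest id) survives.
  Near-duplicate hashing is out of scope; quote-posts with added text
  are not considered duplicates.
- **Timestamps** are interpreted in UTC and window endpoints are
  inclusive, so a Dec 16–Feb 13 window spans exactly 60 calendar days.
- **Language filtering** trusts metadata; records without a tag are
  kept by default (configurable) and no language-identification model
  is bundled.

## tf-idf encoding

The default weight is the classical unsmoothed form
`v_ij = n_ij · ln(N / N_i)`. Words occurring in every document get
exactly zero weight; the natural logarithm is used since the base only
rescales the matrix and is absorbed by the factorization. A smoothed
variant (`ln((1+N)/(1+N_i)) + 1`) and L2 column normalization are
available behind flags. Tokenization lowercases, strips URLs and
@-mentions, keeps hashtags as bare words, removes punctuation,
stopwords and single-character tokens; the stopword list ships as a
data file and every step is configurable. Vocabulary order is
lexicographic for determinism; words are retained when
`min_df ≤ df ≤ max_df_frac · N` (defaults 2 and 0.95).

## Online NMF

`V ≈ W H` is fitted in sequential mini-batches: for each batch, the
loadings `H` are updated with the previous dictionary fixed, then the
dictionary `W` is refreshed with the loadings fixed. Both block updates
are multiplicative (Lee–Seung Frobenius form), which preserves
nonnegativity and never increases the batch objective; the per-batch
objective trace is logged and asserted non-increasing in the tests.

Numerical choices:

- **Initialization** draws `W` (and each batch's `H`) uniform(0,1) from
  the seed; document order is as read (no shuffling) so runs are exactly
  reproducible. A shuffle flag exists, default off.
- **Stopping**: inner iterations stop at `inner_iters` (default 60) or
  when the relative objective decrease falls below `tol` (default 1e-5).
- **Scale ambiguity** is removed by L2-normalizing dictionary columns
  after each batch, making argmax assignment and top-word lists well
  defined.
- **A small epsilon** (1e-12) guards the multiplicative denominators.
- **Inference** against the final dictionary uses per-column nonnegative
  least squares rather than multiplicative updates, so loadings are
  exact minimizers; all-zero documents get zero loadings and an
  `unassigned` sentinel (−1) rather than an arbitrary topic.
- **Ties** in the argmax go to the smallest topic index.
- **Topic filtering** keeps topics whose share of assigned documents is
  at least the uniform ratio `1/K` (equality kept, with a 1e-12 guard);
  unassigned documents are excluded from the denominator.
- One pass over the corpus is the default; `n_passes` is configurable.

The single-batch case reduces exactly to batch multiplicative-update
NMF, which the tests verify against an independent reference
implementation at equal iteration budget, and against a truncated-SVD
oracle in the rank-1 case (valid by Perron–Frobenius).

A caveat found during benchmarking and worth knowing: when `K` exceeds
the number of genuine topics, plain Frobenius NMF has no pressure to
leave surplus columns empty — it may split one topic's documents across
two near-parallel columns, in which case both halves can fall under the
`1/K` cutoff. The retention benchmark therefore evaluates the filter on
ground-truth assignments (where "planted vs noise topic" is well
defined), while dictionary quality is evaluated by best-match cosine,
which is robust to splitting.

## Two-step sentiment

**Polarity.** The scorer sums matched token valences, with a negation
within the two preceding tokens flipping and damping the valence
(× −0.74) and a booster immediately before it shifting the magnitude
(±0.293), then squashes the sum by `s/√(s² + 15)` into [−1, 1]. Labels
use the standard social-media thresholds: ≤ −0.05 negative, ≥ +0.05
positive, neutral between. The bundled mini-lexicon (≈50 entries,
TSV) covers the synthetic emotion vocabularies plus a few generic
terms and makes the unit tests exact; any larger lexicon in the same
TSV format can be dropped in for production runs.

**Emotions.** Zero-shot assignment by cosine similarity between the
text embedding and the embeddings of the five bare emotion words.
The default *gated* mode restricts candidates by polarity — the
emotion taxonomy itself is polarity-partitioned (joy/hopefulness
positive; anger/fear/sadness negative; neutral its own class) — so no
positive post can ever be labeled angry and vice versa; this partition
is asserted as an invariant on every generated corpus. A *global* mode
instead takes the argmax over all five cosines with the compound score
occupying the neutral slot of the emotion matrix; it is kept as a
documented alternative (with the caveat that a compound is not a
cosine, so the two scales are not strictly comparable). Ties resolve
in the fixed order anger, fear, sadness, joy, hopefulness. A
zero-embedding text falls back to neutral with a logged warning.
Anchor prompts are configurable (e.g. `"this text expresses {emotion}"`)
but default to the bare words.

## Trends and stationarity

Daily series are proportions on a contiguous calendar grid. Days with
zero volume in scope yield *missing* values, not zeros — silent days
must not fabricate sentiment. Per day, the six emotion proportions sum
to one wherever volume is positive. "Weekly" curves are centered 7-day
rolling means with shrinking windows at the boundaries; a
calendar-week aggregation was considered and rejected as it decimates
the 60-day window to 9 points.

The stationarity test is the augmented Dickey-Fuller regression with a
constant term and no deterministic trend (proportions have a nonzero
mean and no a-priori trend specification), lag order selected by AIC up
to `⌊(n−1)^(1/3)⌋`. Rejection at α = 0.05 is reported as "stationary".
Constant series and series with fewer than 10 points are errors, not
results. The test runs on raw daily proportions, not smoothed ones
(smoothing induces autocorrelation that the test would have to undo).

## Synthetic benchmarks

The generator emulates the shape of a keyword-collected 60-day corpus:

- Each document gets one dominant topic from `K_true` planted
  topic-word distributions — a diffuse Dirichlet(0.1) base with 60% of
  the mass concentrated on 10 disjoint anchor words per topic — with
  token count ~ Poisson(12), minimum 3.
- Emotions are drawn from a per-day mixture schedule (stationary, or
  linearly drifting for chosen emotions, renormalized daily); emotional
  documents get 1–3 words injected from disjoint per-emotion lexicons
  whose valences drive the polarity scorer to the implied sign.
- A corpus keyword ("vaccine") is injected with probability 0.9 so
  keyword filtering is exercised; timestamps are uniform within the
  assigned day; everything is deterministic under the seed.

Presets fix the study conditions: `easy` (5 topics, 200-word
vocabulary, 2000 documents — the recovery benchmark), `stationary` and
`drift` (6000 documents ≈ 100/day, so daily proportions have enough
volume for the unit-root test to have power at 60 points; `drift` ramps
the sadness share linearly from 0.05 to 0.35 before renormalization).

The **toy embedder** maps a text to the 5-vector of per-emotion lexicon
word counts, L2-normalized; each bare emotion word maps exactly to its
basis vector. This makes zero-shot classification analytically exact on
synthetic data — deliberately so: the benchmarks verify the pipeline's
plumbing and decision rules, not the semantic quality of any real
embedding model. Real corpora have none of these conveniences
(emotion vocabulary is not disjoint, polarity cues are not injected,
topics are not anchored), so passing benchmarks bound implementation
correctness, not field performance.

## Problem sizes

The shipped benchmarks run at the preset sizes above (2000–6000
documents, vocabularies around 200–230 words after filtering, K = 8
fits with up to 400 inner iterations), chosen so the full suite and the
reproduction script complete in seconds while keeping multinomial
noise small relative to the planted effects (topic shares 0.19–0.20
versus a 0.125 retention cutoff; drift amplitude ~0.25 versus daily
sampling noise ~0.04).

## Known limitations

- Deduplication is exact-match only; paraphrased bot content passes.
- The mini-lexicon is tiny by design; production polarity should load a
  full social-media lexicon via `load_lexicon`.
- No embedding model is bundled; real emotion classification requires
  registering a sentence embedder.
- Topic count `K` is an input, not selected by the package; with `K`
  well above the true topic count, surplus-column splitting (see the
  NMF caveat) can push genuine topics under the ratio cutoff.
- The ADF test at 60 daily points has limited power; borderline
  stationary series can fail to reject under unlucky sampling.
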