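# Methods

## The pipeline and its assumptions

The package treats disease surveillance from short public messages as a
fixed sequence of estimators:

filter → geolocate → correct → topic model → theme model → prevalence → compare.

The analysis assumes (i) a message mentions a disease iff it contains a
lexicon keyword — recall of the lexicon is *not* estimated, only the
precision of each keyword; (ii) an author posts from one home county;
(iii) content structure is describable by an admixture model (LDA) whose
topics cluster into a small number of themes; (iv) claims-based
unique-patient counts are an adequate prevalence reference. Each
assumption is inherited by the synthetic generator, which is exactly
what makes planted-structure recovery a meaningful check of the
estimators and *not* a check of those assumptions against real data.

## Keyword filtering and correction factors

Tokenization is NFKC-normalized, lowercased, punctuation-stripped;
hashtags and mentions survive as single tokens and URLs become a
`<url>` sentinel. Matching is per disease, left-to-right,
longest-phrase-wins, with matched token runs consumed, so "breast
cancer" never double-counts its substring keyword "cancer".

Two counts matter and differ deliberately: *n<sub>k</sub>* counts
messages containing keyword *k* (a message with two different keywords
of one disease enters both n terms), while the per-disease raw count
de-duplicates messages. The corrected count Σ w<sub>k</sub>n<sub>k</sub>
therefore can, for pathological lexica, exceed the de-duplicated raw
count; the package warns when it happens rather than redefining the
estimator. The per-disease "correction factor %" in report tables is
the derived ratio corrected/raw, never an input — corrected counts are
always built from per-keyword factors.

Annotation samples are uniform without replacement, capped at the
available messages, default size 30 — small enough for manual review,
with binomial standard error ≤ 0.09 per keyword. In synthetic mode
labels come from the ground-truth sidecar; the exchange CSV format
supports real manual review.

Reported percentages round half-up to 2 decimals and corrected counts
half-up to integers; internal arithmetic is real-valued. Half-up is
used because the bundled published tables were evidently rounded that
way, and the report layer's invariant is that every printed percentage
is recomputable from the printed counts.

## Geolocation

Coordinates are authoritative when they resolve; if a point falls
outside every boundary the free-text location field is tried next (the
alternative — declaring such messages unmapped — discards usable
information for no accuracy gain). The bare-name rule maps a city name
iff max-place population ÷ total same-name population ≥ 0.90 ("at
least 90%"), the name is absent from the common-word exclusion list,
and similarly for bare county names. The threshold is exposed because
its monotonicity (raising it only removes mappings) is a tested
invariant.

The bundled exclusion list (~300 common English words) and the
synthetic rectangular county boundaries are editable stand-ins; real
shapefiles and full per-language top-1000 word lists can be substituted
without code changes.

## Topic model

LDA is fitted by collapsed Gibbs sampling (numba inner loop):
assignment z<sub>i</sub> resampled from (n<sub>dk</sub>+α)(n<sub>kw</sub>+β)/(n<sub>k</sub>+Vβ),
φ and p(topic) estimated from post-burn-in count averages. Defaults
α = 50/K, β = 0.01, 400 iterations, 150 burn-in — Mallet-style
conventions, adequate for desk-scale corpora (the demo uses 150/50).
The per-iteration collapsed joint log-likelihood is recorded; its
smoothed trend is a convergence diagnostic and a regression test.

A single chain can stick in a label-merged mode when the posterior is
strongly multimodal (e.g. two topics splitting one planted block).
`fit_lda(n_restarts=...)` runs independent chains from derived seeds
and keeps the best mean post-burn-in log-likelihood; the recovery
experiments use 3 restarts. Note that 50/K is a poor α at small K
(at K=3 it swamps 15-token documents), so the block-recovery
experiment sets α = 0.1 explicitly.

Vocabulary: author frequency is computed over *distinct* author ids
(an author posting a word 100 times counts once), threshold ≥5% of
authors, all lexicon tokens removed unconditionally.

Per-message distributions use the word-level Bayes inversion rather
than per-document Gibbs inference: p(t|msg) = Σ<sub>w</sub>
p(w|msg)p(t|w). This makes loads a pure function of the fitted model
and the token multiset — invariant to token-list duplication, cheap,
and exactly reproducible. Messages with no in-vocabulary tokens are
flagged undefined and excluded from correlations.

Correlation of loads with binary disease labels is ordinary Pearson
(equivalently point-biserial), two-sided p from the t transform, BH
applied once over the whole (disease, topic) family with undefined
pairs (zero variance) excluded. Significance is BH-adjusted p < .001 —
the threshold is applied after adjustment, the stricter of the two
possible orderings.

## Theme model

The K×V matrix φ is factorized by multiplicative updates from an
NNDSVD initialization (zeros filled with mean(X)/100, SVD signs fixed
deterministically), minimizing Frobenius error; the per-iteration
residual trace is kept because monotone non-increase is part of the
operation's contract and is asserted in tests. sklearn's NMF serves as
an independent oracle for the objective value, not as the
implementation. Theme rank T=10 by default; theme *names* are pure
configuration labels with no computational role.

p(word|theme) is row-normalized H; the theme prior is proportional to
W's column mass; p(theme|word) follows by Bayes' rule. Message theme
loads mirror the topic-load formula; the hard label is the argmax with
lowest-index tie-break.

p(t|d) uses hard-assignment counts N(d,t)/N(d) (integer message counts
are the natural reporting unit); an expected-mass variant (mean
probability mass) is available behind the `soft` flag. PMI uses the
same joint counts over the disease-message universe — a message about
two diseases contributes to both — with natural log by default and a
configurable base, since the log base is a reporting convention. Zero
joint counts give NA rather than −∞.

## Prevalence

Patients de-duplicate on (patient, disease, county); every configured
county appears (zero-filled) so the state mean is over all counties.
Both state summaries are always computed: the unweighted mean of county
prevalences, and the pooled share (statewide unique patients ÷
statewide population). They answer different questions and coincide
only for equal county populations (a tested consistency identity); the
volume-vs-prevalence comparison uses the pooled share because the
bundled published headline percentages are statewide ratios.

## The synthetic generator

Each message: an author (fixed county, population-weighted), an
optional injected keyword whose *relevant* flag is Bernoulli with the
configured true precision, a theme drawn from a prior that is biased by
`disease_theme_bias` only for genuinely disease-referencing messages,
one topic from the theme, and 5–25 tokens from the topic (the
platform's historical character limit is honored only loosely).
Irrelevant keyword uses land in unbiased-theme messages, so correction
factors and content structure interact the way ambiguous terms do in
real corpora. Geodata is a configured mix of coordinates, resolvable
location fields, and noise; the gazetteer plants both an always-
ambiguous name and a concentrated-but-excluded name. Claims give each
resident a disease claim with the planted prevalence, plus Poisson
duplicate rows. Ground truth travels in a sidecar stream keyed by
message id — filtering stages never see it.

What the generator does **not** emulate: real English (tokens are
codes; keywords are the only natural-language tokens), author networks
and reposting cascades, temporal bursts, metaphor and sarcasm, or
geographic sampling bias. Passing tests therefore demonstrate that the
estimators recover the structure they target under the model's own
assumptions — they say nothing about lexicon recall or annotation
subjectivity on real platforms.

## Problem sizes and numerical choices

The demo pipeline uses 2,000 messages, 4 counties, K=10, T=4 — chosen
so the full run and its determinism check complete in seconds while
every stage still has estimable structure. Recovery experiments use
120-document block corpora (LDA), 8–12 topic matrices (NMF), 5,000
null pairs (BH), 200 resamples of size 30 (correction factors), and
1,500-message corpora with one 8×-biased (disease, theme) pair (PMI
recovery). Tolerances on sampling-based checks are 3 standard errors
throughout; algebraic identities are checked at 1e-9–1e-12. Ties in
argmax resolve to the lowest index; zero-mass rows/columns in
normalizations fall back to uniform.

## Known limitations

- Keyword recall is unestimated by design; corrected counts bound
  precision only.
- The location-field rule inherits gazetteer quality; population
  concentration is a heuristic, not geocoding.
- The word-level load formula is an approximation to per-document
  posterior inference; it is exact for single-word messages and
  degrades gracefully for short ones, but is not the Gibbs posterior.
- NMF theme recovery can merge planted themes on unlucky seeds at
  small T (observed on ~10% of arbitrary seeds in the PMI-recovery
  scenario); the recovery experiments report this rather than hiding
  it, and multi-restart selection is available for LDA but not
  implemented for NMF (NNDSVD makes its initialization deterministic).
- The bundled lexica, exclusion list, gazetteer, and disease-code table
  are editable synthetic stand-ins, not curated resources.
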