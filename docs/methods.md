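# Methods

`littopics` implements a literature-trend analysis pipeline: bibliographic
records are filtered and summarized, abstracts are reduced to a
document–term matrix (DTM), a latent Dirichlet allocation (LDA) model is
fitted by collapsed Gibbs sampling, the number of topics is chosen by a
harmonic-mean marginal-likelihood criterion, and each topic's yearly
prevalence is tested for a linear trend to call it *hot* (rising) or *cold*
(falling). This note records the model, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Bibliometric summaries

Records carry title, abstract, publication year, journal, document type,
first-affiliation country, citation count and subject categories. Inclusion
filters are conjunctive: subject category intersecting an allowed set, year
inside a window, and (optionally) a non-empty abstract. Yearly output is
counted per calendar year with interior zero-count years retained, and its
trend is an ordinary least squares (OLS) fit of count on year with a
two-sided t-test on the slope; dropping empty interior years would bias the
slope, so they stay in. Journal activity is summarized as
TPD/TP (%) — the journal's share of publications on the focal subject — and
TC/TPD, the mean citations of those publications; both are rounded half away
from zero to one decimal, matching how such tables are printed (Python's
built-in banker's rounding would disagree on exact halves). A journal with
no subject publications has an undefined, not zero, citation mean. Country
attribution uses the trailing-country convention of the first affiliation
address, with a normalization table (e.g. "Peoples R China" → China; the
four home nations → United Kingdom). First-affiliation attribution is the
usual bibliometric surrogate for study origin and is known to misattribute
some multi-country collaborations; the package makes no attempt to do
better.

## Preprocessing

Abstracts are lowercased, split on every non-alphabetic character (so
hyphenated terms split), stop words removed (the Glasgow English list,
frozen in `littopics/data/stopwords_en.txt`), and stemmed with an
in-package implementation of the Porter algorithm (original 1980 rule set).
Terms whose corpus-wide frequency falls below `min_count` (default 5) are
dropped. The threshold is read as corpus-wide token frequency — not
per-document frequency and not document frequency — which matches common
text-mining practice for this recipe. Documents left empty by filtering are
kept as all-zero rows so row indices stay aligned with publication years;
the LDA fit gives them a uniform topic mixture and flags them, and the
trend stage excludes flagged rows from yearly averages. Lowercasing happens
before stopword matching. The vocabulary is sorted lexicographically, and
the whole pipeline is deterministic.

## LDA and the collapsed Gibbs sampler

The model: document d draws θ_d ~ Dirichlet(α) over T topics; topic k draws
φ_k ~ Dirichlet(β) over V terms; each token draws a topic z ~ Mult(θ_d) and
a word w ~ Mult(φ_z). With θ and φ integrated out, one token at position i
in document d with word v is resampled from

    p(z_i = k | z_-i, w) ∝ (n_dk + α) (n_kv + β) / (n_k + V β),

all counts excluding token i. Point estimates are posterior means over
retained samples: θ̂_dk averages (n_dk + α)/(len_d + Tα) and φ̂_kv averages
(n_kv + β)/(n_k + Vβ). Averaging within a single chain is safe at desk
scale because topic identities rarely swap mid-chain; averaging across
chains is not (label switching) and is deliberately unsupported.

Defaults: α = 50/T and β = 0.1 (the Griffiths–Steyvers convention),
2,000 sweeps with 1,000 burn-in and a thinning lag of 10, one seeded
generator stream. All are configurable. Note that θ̂ is shrunk toward
uniform by the prior — with α = 50/T and ~50-token abstracts the shrinkage
factor is about len/(len + 50) ≈ 0.5 — so fitted prevalence slopes are
attenuated relative to generating slopes; trend *direction* and
significance are unaffected in the validated regimes.

The sweep kernel is compiled with numba when available, with an equivalent
pure-Python fallback. Two likelihood quantities are exposed: the
complete-data log likelihood Σ n_dk log θ_dk + Σ n_kv log φ_kv (0·log 0
treated as 0; a zero probability against a positive count returns −∞), and
the collapsed word log likelihood log P(W|z, β) obtained from the
Dirichlet-multinomial identity, used by model selection.

## Choosing the number of topics

For each candidate T a chain is run and log P(W|T) is estimated from the
retained samples' collapsed word log likelihoods ll_s by the harmonic-mean
identity, computed in the log domain:

    log P̂(W|T) = −( logsumexp(−ll_s) − log S ).

The estimator is exactly translation-equivariant and returns the constant
on constant input, but it is high-variance and optimistically biased in
general; the validation suite therefore anchors it against brute-force
enumeration on tiny instances (≤ 12 tokens, ≤ 3 topics), where the exact
evidence is the log-domain sum of P(W|z, β) P(z|α) over all T^N assignment
vectors. Ties within 1e-9 nats resolve to the smallest T, and per-candidate
seeds derive deterministically from the master seed.

One selection-specific choice deserves emphasis. With the flat document
prior α = 50/T at desk scale (hundreds of documents, V·β small relative to
per-topic token counts), the evidence estimate increases monotonically in T
on separable corpora: splitting a topic's vocabulary in two raises
log P(W|z) by roughly N_k log 2 (a log-Γ convexity gain), and the flat
prior imposes no countervailing cost, so the selector runs off the top of
the grid. Under a sparse document prior the assignment prior charges each
document about |log α| per duplicated topic, cancelling the split gain and
restoring an interior optimum. Selection experiments therefore use
α = 0.02, β = 1.0; these are properties of the selection procedure, not of
the final fit, and both remain configurable.

## Hot and cold topics

A topic's prevalence signal is the mean of its θ̂ column over the documents
of each year (years with no documents are omitted, not imputed; flagged
empty documents are excluded). The trend is an unweighted OLS of that
series on calendar year with a two-sided t-test on the slope (n − 2 degrees
of freedom). A topic is *hot* (or *cold*) at a level when its p-value is ≤
the level — equality counts — and its slope is positive (negative);
zero-variance series and series of fewer than three years have an undefined
p-value and are never flagged. The summary table tallies negative,
positive and total calls at the four conventional levels 0.05, 0.01, 0.001,
0.0001; by construction counts are non-increasing as the level tightens and
totals are additive. No multiple-testing correction is applied by default
because the per-level tally is the object of interest; a
Benjamini–Hochberg option (`fdr=True`) is available and is strictly more
conservative. Regression is unweighted by yearly document count; weighting
is a plausible alternative the package does not implement.

## Synthetic corpora

The generator draws corpora from the exact process the analysis assumes,
with a year-dependent prevalence: documents of year y use
a_y = base_alpha + trend_slopes · (y − y0) as their Dirichlet parameter.
When the slope vector sums to zero, Σa_y is constant and the expected
prevalence of topic k drifts linearly at exactly trend_slopes_k / Σ
base_alpha per year, which makes trend-recovery experiments analytically
checkable. Weights are validated to stay positive across the whole year
span at spec time. Topic–word rows are symmetric Dirichlet draws or, for
well-separated topics, rows with disjoint equal-width vocabulary blocks.
Document lengths are Poisson (default mean 50, floored at 1), emulating
short abstracts. Default shape: 28 years × 10–11 documents/year (~300
documents), 60 terms, 3 topics — small enough that every validation
experiment runs in seconds yet large enough for the trend tests to have
essentially full power at the injected effect sizes.

What the generator does *not* emulate: natural-language word order and
syntax (irrelevant to a bag-of-words model), Zipfian vocabulary growth,
topic correlation, citation or journal structure, and the scale of a real
literature (tens of thousands of abstracts, 100+ topics). Passing recovery
tests therefore demonstrates correctness of the machinery under the model's
own assumptions, not robustness to real-corpus misspecification.

Estimated topics are aligned to true ones by maximizing total cosine
similarity over one-to-one assignments (Hungarian algorithm, optimal for
any topic count; the estimated set may be larger than the true set).

## Validation experiments and problem sizes

`littopics.experiments` defines the repeatable studies that both the test
suite and `scripts/acceptance.py` run:

- **Journal-table arithmetic** on the bundled 20-journal activity table:
  all 40 one-decimal ratio cells must reproduce exactly.
- **Sampler exactness** on a 2-document, 6-token, T = 2, V = 3 instance
  (α = 0.5, β = 0.1): 20,000 draws thinned at lag 20 after 1,000 burn-in
  sweeps are compared with the exhaustively enumerated 64-state posterior
  by total-variation distance. Thinning matters: consecutive sweeps are
  autocorrelated enough that mode-time imbalance alone can dominate the
  distance even for an exact sampler (verified by a 500k-sweep run driving
  TV to 0.003).
- **Evidence estimator** on the same instance with β = 0.5: the
  harmonic-mean estimate from 5,000 thinned samples against brute-force
  enumeration. β = 0.5 keeps the estimator's intrinsic Monte-Carlo
  spread small so the comparison tests accuracy rather than variance.
- **Topic-count recovery**: 10 corpora (200 docs, 3 disjoint topics,
  60 terms), grid 1–6, selection priors as above.
- **Trend calibration and recovery**: 1,000 flat noisy series (28 years)
  for the null flag rate at 0.05; 10 replicates of 5 rising / 5 falling /
  10 flat series (|slope| 0.003/yr, noise sd 0.0005) for detection at 0.01.
- **End-to-end**: simulate (~308 docs, one rising, one falling, one flat
  topic) → fit → Hungarian match (cosine) → trend directions.

## Known limitations

- The harmonic-mean evidence criterion is noisy and biased; it is kept
  because it is the standard companion of the collapsed sampler for this
  task, but grids of adjacent T values can be statistically
  indistinguishable on small corpora.
- Single-chain inference: no convergence diagnostics beyond the
  log-likelihood trace, no cross-chain agreement checks.
- The Porter stemmer implements the original rule set; extensions found in
  some toolkits (e.g. special-casing of *-logi*, *-bli*) are intentionally
  absent.
- The field-tagged reader covers the common two-letter-tag export layout;
  exotic vendor variants may need the delimited fallback.
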