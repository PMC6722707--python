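# littopics

Topic-model based trend mining for bibliographic corpora.

Given a set of publication records (e.g. a Web of Science field-tagged
export), `littopics` answers two questions a research-field overview needs:
*what topics does this literature contain?* and *which of them are rising
("hot") or falling ("cold") over time?* It was built around the workflow
used to map diatom research — unicellular silica-shelled algae whose
literature spans ecology, paleolimnology and water-quality assessment — but
nothing in the pipeline is specific to that field.

The pipeline:

1. **Ingest** — parse field-tagged or tab-delimited exports into records;
   filter by subject category, year window, and abstract availability;
   summarize yearly output (with OLS trend), journal activity
   (TPD/TP %, TC/TPD), and country/region distribution.
2. **Preprocess** — lowercase, strip punctuation/digits, remove stop words,
   Porter-stem, drop terms occurring fewer than 5 times corpus-wide, and
   count into a sparse document–term matrix.
3. **Model** — latent Dirichlet allocation fitted by collapsed Gibbs
   sampling. Each document d mixes topics through θ_d ~ Dir(α); each topic
   k is a word distribution φ_k ~ Dir(β); tokens are resampled from the
   collapsed conditional p(z_i = k) ∝ (n_dk + α)(n_kv + β)/(n_k + Vβ).
   θ̂ and φ̂ are posterior means over thinned post-burn-in samples.
4. **Select T** — estimate log P(W|T) over a candidate grid by the
   harmonic mean of sampled collapsed word log-likelihoods,
   −(logsumexp(−ll_s) − log S), and take the argmax.
5. **Trends** — average θ̂ per topic per publication year, regress on year,
   and call topics hot/cold at the 0.05, 0.01, 0.001, 0.0001 levels from
   the two-sided slope t-test.

A synthetic-corpus module generates ground-truth corpora from the same
generative process with linearly drifting topic prevalence, so every stage
can be validated against known truth; `match_topics` aligns fitted to true
topics by Hungarian assignment on cosine similarity.

## Worked example

```python
import numpy as np
from littopics import (SyntheticSpec, generate_corpus, CollapsedGibbsLDA,
                       match_topics, TopicTrendAnalyzer)

spec = SyntheticSpec(
    n_topics=3, n_terms=60, years=list(range(1991, 2019)), docs_per_year=11,
    doc_length=50, disjoint_topics=True,
    base_alpha=np.array([1.0, 3.0, 2.0]),
    trend_slopes=np.array([0.08, -0.08, 0.0]), seed=0)
dtm, truth = generate_corpus(spec)

model = CollapsedGibbsLDA(n_topics=3, n_iterations=400, burn_in=200,
                          sample_lag=10, random_state=1).fit(dtm)
mapping, sims = match_topics(truth.phi_true, model.components_)
print("matched cosine similarities:", np.round(sims, 3))

ana = TopicTrendAnalyzer().fit(model.theta_, dtm.doc_years, model.empty_doc_mask_)
for k in range(3):
    t = ana.trends_[mapping[k]]
    print(f"true topic {k}: slope={t.slope:+.5f}/yr  p={t.p_value:.2e}  -> {t.direction}")
```

prints

```
matched cosine similarities: [1.    0.998 0.999]
true topic 0: slope=+0.00712/yr  p=8.72e-13  -> hot
true topic 1: slope=-0.00644/yr  p=2.01e-09  -> cold
true topic 2: slope=-0.00068/yr  p=2.71e-01  -> none
```

The corpus injected a rising, a falling, and a flat topic; the fitted model
recovers each topic's word distribution (cosine ≥ 0.998 after matching)
and calls every trend direction correctly. The fitted slopes are smaller
than the generating drift of ±0.0133/yr because θ̂ is shrunk toward uniform
by the α prior — direction and significance are what the analysis reads.

The same analysis is available from the shell:

```bash
littopics simulate --topics 3 --terms 60 --disjoint --out syn
littopics fit syn --topics 3 --iters 400 --burnin 200 --out lda
littopics trends lda.theta.tsv syn.years.txt --out tr
```

(`littopics ingest` and `littopics dtm` cover the real-data path from a
bibliographic export to the matrix; `littopics select-t` scans a topic-count
grid.)

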