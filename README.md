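# littopics

Topic-modelling pipeline for bibliographic corpora of research abstracts:
ingest and deduplicate records, clean and stem the text into a
document–term matrix, fit Latent Dirichlet Allocation by collapsed Gibbs
sampling with cross-validated selection of the number of topics, and derive
the scientometric statistics used to map a research field over time —
decadal topic prevalence, topic co-occurrence, topic generality, per-topic
popularity trends (Poisson GLMM), journal contribution and country-mention
counts. A synthetic corpus generator with known ground truth makes every
stage testable without access to proprietary literature databases.

It is aimed at ecologists and scientometricians running systematic maps of
a literature (for example, three decades of research on phenological
responses to a changing climate) who want the whole chain — screening
bookkeeping with inter-rater agreement, reproducible text cleaning, LDA
and trend statistics — in one seeded, deterministic pipeline.

## The models

**LDA.** Each document *d* mixes *K* topics with weights
θ_d ~ Dirichlet(α); each topic *k* is a distribution φ_k over the *V*
vocabulary terms, φ_k ~ Dirichlet(β). The collapsed Gibbs sampler
integrates θ and φ out and resamples each token's topic from

    p(z = k | rest) ∝ (n_dk + α) · (n_kv + β) / (n_k· + Vβ)

Held-out fit is measured by document-completion perplexity
exp(−mean per-token log-likelihood), and the number of topics is chosen by
document-level block cross-validation over a grid of candidate *K*
(default grid 10, 20, 30, 40, 50, 60, 100, 200).

**Popularity GLMM.** Per-topic yearly article counts follow a Poisson
GLMM with log link: log E[y_kt] = μ + γ·t̃ + b0_k + b1_k·t̃ with
(b0_k, b1_k) bivariate normal and t̃ the centred/scaled year. A positive
random intercept b0 marks a popular topic, a positive random slope b1 a
rising one. Estimation maximises the Laplace-approximated marginal
likelihood (the same approximation lme4's `glmer` uses, against which the
fitter is cross-checked in the test suite).

## Worked example

```python
from littopics import (SimulationConfig, generate_corpus, LDA,
                       cross_validate_k, build_counts, PoissonGLMM)
from littopics.preprocess import clean_corpus
from littopics.synthetic import topic_recovery_score

config = SimulationConfig(K_true=5, V=500, D=500, mean_doc_length=100,
                          alpha_true=0.1, beta_true=0.01, seed=42)
records, truth = generate_corpus(config)
dtm, vocab = clean_corpus(records)

result = LDA(dtm.fitted(), K=5, alpha=0.1, beta=0.01).fit(
    n_iter=2000, burn_in=1000, seed=42)
score, _ = topic_recovery_score(result.phi, vocab.terms, truth)
print(f"Hungarian-matched mean cosine to true topics: {score:.3f}")

cv = cross_validate_k(dtm.fitted(), k_grid=[2, 5, 10], folds=3,
                      alpha=0.1, beta=0.01, n_iter=300, burn_in=150, seed=42)
print(cv.summary())

counts = build_counts([r.year for r in records], result.theta)
fit = PoissonGLMM(counts).fit()
print(f"GLMM: mu={fit.mu:.3f} gamma={fit.gamma:.3f}")
```

prints

```
Hungarian-matched mean cosine to true topics: 1.000
block cross-validated perplexity
     K    mean perplexity
     2             30.579
     5             16.030 <- chosen
    10             15.310
argmin K = 10; elbow K = 5; rule = elbow
GLMM: mu=1.204 gamma=-0.000
```

The fitted topic–word distributions recover the generating topics
essentially exactly (cosine 1.000 after optimal matching); cross-validated
perplexity drops sharply from K=2 to the true K=5 and only marginally
beyond, so the elbow rule selects 5 while the argmin (here 10) is also
reported — the selection rule is always named, never silently applied.
The GLMM intercept μ is the log of the mean articles-per-topic-per-year;
this corpus has no injected trend, so γ ≈ 0.

The same stages are available as a CLI:

```bash
littopics simulate --seed 1 --out corpus.jsonl
littopics clean corpus.jsonl --out dtm/
littopics cv dtm/ --grid 2,5,10 --folds 3
littopics fit dtm/ --k 5 --seed 1 --out model/
littopics metrics --model model/ --records corpus.jsonl --out metrics/
littopics geo corpus.jsonl --out countries.tsv
```

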