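# Methods

This note documents the models, the cleaning recipe, the synthetic-data
design and the numerical choices behind `littopics`, in the order the
pipeline runs.

## Screening bookkeeping and agreement

Screening (deciding whether an article belongs in the corpus) is a human
judgement; the package only stores decisions, samples a seeded
double-screening subset (default 20% of records) and computes Cohen's
kappa κ = (p_o − p_e)/(1 − p_e) between the two reviewers, where p_o is
the observed proportion of agreement and p_e the chance agreement implied
by the raters' marginals. When both raters are constant and identical,
p_e = 1 and κ is undefined; the package raises an explicit error rather
than returning a number.

Deduplication removes records whose normalised title (casefolded,
punctuation stripped, whitespace collapsed) **and** year match an earlier
record; the first occurrence wins and removals are logged. Reference
managers do not publish their duplicate heuristics, so this rule is a
stated approximation; an optional fuzzy mode (Levenshtein distance ≤ 2 on
the normalised title, same year) exists behind a flag and is off by
default because silent fuzzy merging is riskier than a missed duplicate.

## Text cleaning

The pipeline order is fixed: lowercase → delete search-term phrases →
hyphens and forward slashes to spaces → strip remaining punctuation →
tokenise on whitespace → drop number-words, stop-words and publisher
boilerplate → Porter-stem each surviving token. Search-term patterns are
written as stems ("climat* chang*") and matched prefix-wise against the
raw text, with a second pass over the stemmed token stream as a safety
net. Terms appearing in fewer than `min_doc_frequency` documents
(default 6, i.e. terms in five or fewer documents) are removed in a single
pass; documents emptied by cleaning are kept as all-zero rows, flagged,
and excluded from model fitting. Vocabulary order is lexicographic so all
downstream output is deterministic.

The stop-word list is a standard English list with a small documented
extension, and the number-word and publisher-term lists are shipped as
editable data files; all three are configurable because no canonical
version of such lists exists. The stemmer implements the classic Porter
suffix-stripping algorithm (including the author's two later departures);
it is implemented in-package and validated against the algorithm's
published worked examples.

## LDA by collapsed Gibbs sampling

Hyperparameters default to α = 50/K and β = 0.1 (the common conventions
for Gibbs LDA), n_iter = 2000 sweeps with burn_in = 1000, single chain.
Point estimates are read off the final count state,

    φ_kv = (n_kv + β)/(n_k· + Vβ),   θ_dk = (n_dk + α)/(n_d· + Kα),

with an option to average over every m-th post-burn-in sweep instead. The
joint collapsed log-likelihood is traced so callers can judge mixing; no
automatic convergence detection is attempted.

Determinism and exchangeability: every document owns a PCG64 stream keyed
by a stable blake2b hash of its id mixed with the user seed, and documents
are visited in sorted-id order within each sweep. A fixed seed therefore
gives bit-identical output, and permuting the input rows permutes θ rows
identically while leaving φ unchanged — a property the tests assert
exactly.

**Perplexity.** Held-out documents are scored by document completion: the
document's tokens (expanded in vocabulary order) are split alternately
into a fold-in half and an evaluation half; the fold-in half estimates
θ_d by short Gibbs runs (default 50 iterations) against fixed φ, and the
evaluation half is scored under Σ_k θ_dk φ_kv. A DTM carries no token
order, so the "first half" of a document is realised as the even-indexed
positions of the deterministic expansion — an interleaved split that
balances content across halves. Held-out terms outside the model
vocabulary are excluded with a warning and a count.

**Model selection.** Documents are shuffled once (seeded) and split into
contiguous blocks (default 5 folds); for every candidate K and fold the
model is fitted on the remaining blocks and scored on the held-out block.
Cells where K reaches the training vocabulary or document count are
marked invalid and excluded. Both the argmin of mean perplexity and a
tolerance-based elbow (the last K before relative improvement first falls
below `elbow_tol`, default 0.05) are always reported, and `chosen_K`
follows a named rule — perplexity curves flatten rather than turn, so a
silent argmin would systematically overfit K.

## Derived statistics

All derived statistics consume θ (rows sum to 1) plus per-article
metadata and are deterministic.

- **Decadal prevalence**: per topic, θ weights summed over articles within
  each decade (defaults 1990–1999, 2000–2009, 2010–2019); articles outside
  the configured decades (or with missing year) are excluded and counted.
  Column sums equal per-decade article counts, a conservation law the
  tests assert. Within-decade ranks are also emitted.
- **Co-occurrence**: θ is log10-transformed (hence θ must be strictly
  positive — Dirichlet smoothing guarantees this; a zero raises an error
  pointing at smoothed estimates); d_ij is the Euclidean distance between
  topics i and j's log-weight profiles across articles, and similarity is
  1 − d/d_max with d_max the largest off-diagonal distance, so the most
  dissimilar pair scores 0 and identical profiles score 1. A min–max
  variant is offered, and raw distances are always emitted alongside.
- **Generality**: per article the highest-weight topic is selected (ties
  broken by lowest topic index, logged); each topic reports its mean
  weight when selected vs. when not. Never-selected topics report a
  missing selected mean, not 0.
- **Article–topic frequency** is emitted in both plausible constructions —
  argmax counts per topic and the per-topic histogram of θ weights —
  because the figure it supports can be read either way.
- **Journal contribution**: journals ranked by article count (ties
  lexicographic), cumulative top-N shares, and per-journal topic profiles
  (mean θ and argmax counts).

## Popularity GLMM

Counts y_kt (articles per topic per year, argmax assignment with the same
tie policy as above; a weighted θ-sum variant exists behind a flag) follow

    y_kt ~ Poisson,  log E[y_kt] = μ + γ t̃ + b0_k + b1_k t̃,
    (b0_k, b1_k) ~ N(0, Σ),

with t̃ the year centred and scaled to unit variance (sign-based
classification is invariant to this; scaling improves conditioning). The
marginal likelihood is approximated by Laplace: topics are conditionally
independent, so each topic's 2-D integral is evaluated at its conditional
mode (damped Newton, tolerance 1e-10) and the outer parameters
(μ, γ, log σ0, log σ1, atanh ρ) are maximised with L-BFGS-B — fully
deterministic. Conditional modes double as the empirical-Bayes random
effects. The fitter reproduces lme4's `glmer` Laplace fit on the same
data to ~1e-3 in the fixed effects and variance components (frozen
cross-check in the tests). An uncorrelated-random-effects variant
(`fit(correlated=False)`) fixes ρ = 0.

Topics are classified by random-effect signs: hot (b0>0, b1>0),
declining-popular (b0>0, b1<0), rising-niche (b0<0, b1>0), cold (both
negative); exact zeros are labelled boundary.

Shrinkage: the empirical-Bayes effects are smaller than the unshrunk
per-topic GLM deviations in the prior-metric norm b0²/σ0² + b1²/σ1² for
every topic (an exact property of the penalised optimum, asserted in the
tests). Componentwise shrinkage can fail by small margins because the
Poisson weights and the estimated prior correlation couple intercept and
slope, so it is only asserted in aggregate.

## Country mentions

Matching is literal, token-boundary anchored and case-insensitive on the
raw (pre-cleaning) abstract, with an alias file (UN member states plus
common variants such as UK/Britain and USA/America) shipped as editable
YAML. An article counts once per country regardless of repeats; an alias
mapping to two countries is a configuration error. Names that are
countries only in some contexts (Georgia, Jordan, Chad, Turkey, …) match
only when capitalised, with an opt-out flag. Known limitation: a name
contained in a longer name ("Ireland" inside "Northern Ireland", "Korea"
inside "North Korea") still matches the shorter country; resolving that
needs contextual disambiguation out of scope here. The choropleth is
rendered as a simple bar chart — the TSV of counts is the canonical
output.

## Synthetic corpora

The generator emulates the kind of corpus the pipeline targets: D = 500
abstracts of Poisson mean length 100 over a V = 500-term vocabulary,
K_true = 5 topics with document-topic concentration α = 0.1 and
topic-word concentration β = 0.01 (short, topically focused abstracts;
sparse, well-separated topics), years 1990–2019, ~20 journals with
Dirichlet-multinomial shares. Per document, the Dirichlet prior is tilted
by a per-topic softmax trend in the (scaled) year — topics stay fixed
while their prevalence drifts, matching the analysis's own assumption.
Tokens are rendered as stem-like pseudo-words ("w0001") so recovery tests
do not depend on stemmer behaviour; decoy stop-words, spelled-out
numbers, hyphenated merges and publisher boilerplate are injected
separately (with exact counts returned) to exercise the cleaning
pipeline. Identical (config, seed) yields byte-identical corpora.

What the generator does **not** emulate: natural English morphology and
syntax, citation structure, abstract-length drift over time, journal-topic
correlation, or database-specific metadata noise. Passing recovery tests
therefore demonstrates the correctness of the inference machinery under
the model's own assumptions, not robustness to real-world abstract text.

## Problem sizes used in the checks

The exact oracles (Gibbs conditional vs. exhaustive enumeration;
perplexity vs. straight-line recomputation; derived statistics vs. brute
force) run on instances small enough to enumerate (2 documents × 3 words;
≤10-document θ matrices) and agree to 1e-12/1e-10. Topic recovery fits
K = 5 on the standard synthetic corpus for 2000 sweeps; model selection
cross-validates K ∈ {2, 5} with 3 folds and 300-sweep chains, which is
ample for corpora of this size (the log-likelihood trace plateaus within
~100 sweeps). GLMM recovery uses 40 topics × 30 years as generated by the
model itself. The end-to-end determinism check runs a 150-document
pipeline twice and compares output bytes.

Note on GLMM slope recovery: with σ1 = 0.1 on the scaled-year scale and
~e² articles per topic-year, the per-topic slope standard error (~0.07)
is comparable to σ1 itself, so the correlation between estimated and true
slopes is information-bounded near σ1/√(σ1² + SE²) ≈ 0.83 — no estimator
can exceed this on average, and lme4 produces the identical values. The
intercept recovery (σ0 = 0.5, correlation ≈ 0.99) and the null case
(σ = 0 ⇒ all |b̂| < 0.1) are not information-limited.
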