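# tricontinuum

Tools for characterizing **continuous heterogeneity** in bulk expression
cohorts — built around the observation that tumors such as high-risk
blastemal-type Wilms' tumors do not fall into discrete clusters but fill a
low-dimensional continuum bounded by a few extreme expression programs
(e.g. stromal, blastemal, and epithelial programs echoing the un-induced
mesenchyme, cap mesenchyme, and early epithelium of the developing kidney).

The package characterizes one cohort from three angles that share a single
latent structure, *samples as convex mixtures of k extreme components*, and
then checks that the three views agree:

1. **Archetypes (Pareto task inference).** Samples are embedded with
   centered-SVD PCA; the minimum-volume k-simplex enclosing the points
   (triangle for k = 3) is fitted with a soft, SISAL-style containment
   penalty. Its vertices are "idealized" extreme tumors; back-projection
   through the PCA loadings gives each archetype a gene-expression profile,
   characterized by genes with log2 fold change > 2 against *both* other
   archetypes and labeled by hypergeometric enrichment against marker sets
   (GMT).
2. **Topics (grade of membership).** A k-topic model is fitted by Poisson
   NMF — maximize `sum_gi [X_gi log(WH)_gi − (WH)_gi]` with multiplicative
   EM updates followed by cyclic coordinate descent (defaults 100 + 100
   iterations) — and rescaled to loadings `L` (samples × k, rows on the
   simplex: the topic proportions θ₁..θ_k) and factors `F` (genes × k,
   columns are p(gene|topic)). Per-gene topic posteriors invert F by Bayes'
   rule, `p(t|g) = F[g,t] p(t) / Σ_s F[g,s] p(s)` with a uniform prior
   (1/3 for k = 3); genes with posterior > 0.5 form each topic's gene list.
3. **Cell populations (CPM deconvolution).** Each bulk profile is expressed
   as a weighted combination of single cells from a labeled reference via
   repeated linear ν-SVR on random subsets of `modelSize` = 50 cells, with
   enough runs that every cell is drawn ≥ `minSelection` = 5 times;
   abundances are smoothed over the 2D cell-state embedding
   (`neighborhoodSize` = 10 nearest neighbors) and aggregated to cell-type
   proportions.

A first-class **synthetic-data module** generates ground-truthed cohorts
with exactly this structure — Dirichlet mixture weights over archetype
profiles with planted exclusive marker blocks, Poisson or lognormal noise,
and a linked single-cell reference — so every stage is validated by
parameter recovery rather than by eye.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (200 samples × 400 genes, Poisson counts at depth 10⁴, plus a
300-cell reference tied to the same three components):

```bash
python analysis/01_simulate_cohort.py --seed 17
python analysis/02_fit_archetypes.py  --seed 17
python analysis/03_fit_topics.py      --seed 17
python analysis/04_deconvolve.py      --seed 17
python analysis/05_consistency_report.py
```

Output (abridged):

```
PC1+PC2 explain 98.0% of variance
containment fraction 0.995, simplex volume 2.45e+06
vertex recovery error: max 2.62% of triangle diameter
log-likelihood: -2.806e+06 -> -1.629e+05 over 200 iterations
loading recovery: MAE 0.0049 after topic alignment
genes with posterior > 0.5 per topic: {'topic1': 134, 'topic2': 127, 'topic3': 119}
35 SVR runs; every cell drawn >= 5 times
type-proportion RMSE vs planted composition: 0.0236
 archetype  topic type_group  archetype_topic_r  topic_type_r
archetype2 topic1 archetype2           0.988279      0.998005
archetype3 topic3 archetype3           0.992646      0.997888
archetype1 topic2 archetype1           0.987527      0.997937
minimum aligned correlation: 0.988
```

Read: the triangle's vertices land within ~3% of the generating extremes;
the topic model recovers the planted mixture weights to half a percent; the
deconvolution recovers the planted cell-type composition to ~0.02 RMSE; and
the three views agree — for every component, samples close to an archetype
vertex carry a high matched topic loading (r ≈ 0.99) and a high matched
cell-type proportion (r ≈ 0.998).

The same stages are available as a CLI (`tricontinuum simulate | preprocess
| archetypes | topics | deconvolve | run`) and as a single YAML-configured
pipeline, `tricontinuum run --config cfg.yaml`, which writes all stage
outputs plus a hash manifest, so a rerun with the same config reproduces
every file byte for byte.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator's
assumptions, the numerical choices, and known limitations.
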