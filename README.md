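# chemophylo

Comparative chemo-phylogenetics for chemical-communication studies: from
replicate-level chemical peak tables and a species phylogeny to

* **sex-specific and mating-transferred compound calls** (which compounds
  are produced only by males or only by females of a species, and which
  male compounds end up on females after mating),
* **per-compound phylogenetic signal** — maximum-likelihood Pagel's λ under
  λ-transformed Brownian motion, with a Wilcoxon rank-sum comparison of the
  λ distributions between sexes,
* **phylogenetic regressions** linking chemical production to neuronal
  detection: PGLS across branch-length transformation models with BIC
  selection for continuous traits, and a phylogenetic logistic regression
  with parametric-bootstrap p-values for binary presence/absence,
* **the olfactory communication network** — a directed detector → producer
  graph per trichoid sensillum class (at1/at4) built from single-sensillum
  response matrices, with a per-species olfactory clustering coefficient,
  self-loop summaries and an at1-vs-at4 Mann-Whitney comparison,
* **reference-genome selection** for short-read mapping via a quality index
  combining annotation completeness, properly-paired rate and mean MAPQ.

It is aimed at chemical ecologists and evolutionary biologists working
with cuticular-hydrocarbon (GC-MS) profiles and electrophysiology across a
clade, e.g. drosophilids. Every input the pipeline consumes can also be
generated synthetically with known ground truth, so the whole analysis is
testable end to end.

## The model at the core

For a continuous trait `y` measured on the `n` tips of a phylogeny, the
Brownian-motion covariance `C` has `C[i,j]` equal to the shared
root-to-MRCA path length and `C[i,i]` the root-to-tip depth. Pagel's λ
rescales shared history:

```
y ~ N(μ·1, σ² C(λ)),    C(λ)[i,j] = λ C[i,j] (i≠j),  C(λ)[i,i] = C[i,i]
```

λ = 1 means trait covariance tracks the phylogeny, λ = 0 phylogenetic
independence. For fixed λ, μ̂ and σ̂² have closed-form GLS/ML expressions,
so λ̂ maximizes the profile likelihood on [0, 1]. PGLS uses the same
`C(λ)` as the error covariance of a regression (`V = I`, `V = C`, or
`V = C(λ̂)`; the transformation is chosen by BIC). The binary-trait
regression models `P(y=1) = logistic(Xβ)` with residual dependence
decaying as `exp(−α·d)` in patristic distance `d`, and tests coefficients
by parametric bootstrap under the fitted null.

## Worked example

Simulate a 12-species study (40 chemical features per sex, 6 replicates
per species and sex), call compounds, estimate per-feature λ and compare
the sexes:

```
$ chemophylo simulate --seed 42 --n-species 12 --n-features 40 --out-dir demo
wrote synthetic bundle to demo

$ chemophylo profiles --peak-table demo/peak_table.tsv --out-dir demo
7 male-specific, 1 female-specific compounds; 11 dimorphic / 1 monomorphic species

$ chemophylo signal --trait-matrix demo/traits_male.tsv \
    --trait-matrix demo/traits_female.tsv \
    --tree demo/tree.nwk --out demo/lambda.tsv
{"statistic": 927.0, "p_value": 0.003332519883669864, "method": "mannwhitney_normal", "n1": 40, "n2": 34}

$ chemophylo network --catalog demo/compound_catalog.tsv \
    --responses demo/response_matrix.tsv --out-dir demo
{"n_edges": 179, "self_loop_totals": {"at1": 11, "at4": 11}, "at1_vs_at4": {"U": 49.5, "p_value": 0.198}}
```

The generator gives male chemical abundances a strong phylogenetic signal
(λ_true = 0.8) and female abundances a weak one (λ_true = 0.2). The
`signal` output above is the two-sided Wilcoxon rank-sum comparison of the
fitted per-feature λ̂ between the sexes: mean λ̂ is 0.38 over the 40 male
features versus 0.14 over the 34 female features, and p ≈ 0.0033 — the
pipeline recovers the male-biased signal. The `network` output counts
supra-threshold detection edges (responses must exceed 10 spikes/s),
self-loops (females detecting their conspecific male compounds) per
sensillum class, and the Mann-Whitney comparison of the per-species
olfactory clustering coefficients between at1 and at4.

The same analyses are available as library calls (`fit_lambda_table`,
`compare_lambda_distributions`, `pgls_fit`/`select_model_bic`,
`phyloglm_fit`, `build_network`, `choose_reference`, …), and the
statistical models are sklearn-style estimators (`PagelLambda`,
`PhylogeneticRegression`, `PhylogeneticLogisticRegression`) with
`fit()` and trailing-underscore fitted attributes. `chemophylo run-all`
executes the whole pipeline from a JSON config.

## Scope

The package starts from peak tables, response matrices and mapping
summaries; peak detection from raw chromatograms, read mapping, tree
inference and compound identification are upstream of it.
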