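# Methods

## Phylogeny and covariance

Trees are read from Newick (dendropy backend) with unique tip labels and
non-negative branch lengths; missing lengths default to 0. The
Brownian-motion covariance `C` is built in one tree traversal:
`C[i,j]` is the root-to-MRCA path length, `C[i,i]` the root-to-tip depth.
Tip order is Newick appearance order and is recorded in
`PhyloCovariance.labels`; every trait vector is aligned by label, never by
position. Trees whose basal node is a polytomy (typically written
unrooted) are used as-is with a warning — re-rooting would change every
root-to-tip path and hence the covariance, so we leave that decision to
the user.

Pagel's λ multiplies the off-diagonal of `C` and is restricted to
[0, 1]: trees with branch lengths in substitutions per site are not
ultrametric, and λ > 1 can break positive semi-definiteness there. Zero-
length branches are permitted; exactly coincident tips make `C` singular,
so likelihood code falls back to a ridge of `1e-10 × trace(C)` when a
Cholesky factorization fails.

## Pagel's λ estimation

The trait model is `y ~ N(μ·1, σ² C(λ))`. For fixed λ,

```
μ̂  = (1ᵀC(λ)⁻¹1)⁻¹ 1ᵀC(λ)⁻¹y
σ̂² = (y − μ̂1)ᵀ C(λ)⁻¹ (y − μ̂1) / n
```

(the ML divisor `n`, matching the profile likelihood, not `n − 1`). λ̂
maximizes the profile log-likelihood: an 11-point grid on [0, 1] locates
the basin, a bounded scalar search (tolerance 1e-6 in λ) refines it, and
ties with a boundary within 1e-9 log-likelihood units resolve to the
boundary, so λ̂ is exactly 0 or 1 in the flat cases. Constant traits are
unidentifiable and raise; `fit_lambda_table` drops them with a count
rather than imputing. λ is estimated on species means by default (the
`level` argument of `standardize_profiles` controls this) — replicate-
level estimation would mix within-species measurement variance into the
evolutionary model.

Distributions of per-feature λ̂ between two trait classes (e.g. male vs
female features) are compared with the unpaired two-sided Wilcoxon
rank-sum test: exact null enumeration when both samples have ≤ 8
observations and no ties, otherwise the normal approximation with tie and
continuity corrections.

## Peak-table processing

Standardization follows standard chemometric practice: per replicate,
relative areas (each peak divided by the replicate total); then a log
transform with pseudocount equal to half the smallest nonzero relative
area in the table (preserves ordering, avoids −∞ for absent features);
then a z-transform per feature across species. Replicates with zero total
area are an error naming the replicate.

"Present" is not quantified by detector hardware alone, so the calling
rule is: a compound is specific to one sex of a species iff its area
exceeds the detection floor (default 0) in at least `presence_frac`
(default 50%) of that sex's virgin replicates **and** in zero replicates
of the other sex — strict absence mirrors presence "in only one sex"
irrespective of quantity. Species with no sex-specific compound are
monomorphic. A male-specific compound is transferred iff it appears on
mated females of a producing species (same presence fraction) while being
absent from virgin females; female-specific compounds are never flagged.
Both knobs (`presence_frac`, `detection_floor`) are exposed.

Species-profile similarity uses the Pearson correlation coefficient r
(pairwise-complete); r² is derivable but r is reported because profile
anticorrelation is informative. PCA is on centered data (scikit-learn);
explained-variance fractions are non-increasing and sum to ≤ 1.

## PGLS and model selection

`β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V` one of: the identity (`OLS_star`,
phylogenetically independent residuals), the full Brownian covariance
(`BM`), or `C(λ)` with λ estimated by ML jointly with the coefficients
(`lambda_ML`). These are the natural nested extremes plus the estimated
transformation. Reported log-likelihoods are full ML (σ² divisor n);
coefficient tests use the unbiased residual scale and t statistics with
`n − k` degrees of freedom, `k` the number of coefficients. BIC is
`k·ln(n) − 2·loglik` with `k` counting β, σ², and λ when estimated; model
selection takes the minimal BIC, ties toward fewer parameters. BIC
*differences* are invariant to affine rescaling of the response.

## Phylogenetic logistic regression

For a binary species trait the model is `P(y_i = 1) = logistic(x_iᵀβ)`
with residual dependence governed by one strength parameter α: the
working correlation between species i and j is `exp(−α·d_ij)` in
patristic distance, which is exactly the tip correlation of a stationary
two-state Markov chain with total switching rate α — the evolving-binary-
trait view of the model.

Estimation: β is first fit under independence by quasi-Fisher scoring
(steps damped to length 2 on the logit scale; coefficients capped at ±15
under quasi-separation, with a warning); α then maximizes a pairwise
composite likelihood — the exact bivariate Bernoulli probabilities
implied by the marginal means and the working correlation, Fréchet-
clipped — over a fixed grid of correlations at the mean distance
(0.95 … 0.01, plus exact independence); β is refit by GEE at the selected
α. The grid's Cholesky factors are cached per tree, which is what makes
bootstrap-heavy runs tractable on one core.

Significance of a coefficient comes from a parametric bootstrap under the
fitted null: the model is refit without that coefficient; `n_boot`
datasets (2000 at study scale; tests use scaled-down replicates) are
simulated from the fitted null — by the stationary two-state chain on the
tree itself when the null is intercept-only, or by a latent-threshold
(Gaussian copula) draw matching the null means and working correlation
when covariates remain — and the two-sided p-value is
`(1 + #{|β̂*| ≥ |β̂|}) / (1 + n_boot)`. Simulating the binary chain rather
than thresholding a Gaussian matters: the chain's tip correlation is on
the same (binary) scale the estimator measures, which is what calibrates
the type-I error. Bootstrap replicates that draw a single class are
counted against rejection (conservative). The bootstrap scheme is
parametric because the null hypothesis concerns a coefficient of a fully
generative model; which coefficient is tested defaults to the first slope
and is configurable.

## Olfactory network

Edges are directed detector → producer per sensillum class, created iff
some male-specific compound of the producer elicits a mean response
*strictly greater* than the exclusion threshold (default 10 spikes/s;
responses at or below it are excluded, and negative/inhibitory responses
never create edges). A producer with several supra-threshold compounds is
counted once. Monomorphic species are nodes (they can detect) but are
never detected. The olfactory clustering coefficient of a focal species
and sensillum is the number of *other* species detected divided by all
other species in the panel (`n − 1`), so 0 means no species detected and
1 all of them; self-loops (conspecific detection) enter neither side of
the fraction and are summarized separately. The at1-vs-at4 comparison is
the unpaired two-sided Mann-Whitney U over species — the coefficients are
paired by species, but the unpaired test is the conventional reporting
choice for this statistic and is what we implement; the pairing structure
is noted here for users who prefer a signed-rank alternative.

## Reference-quality index

`index = completeness × P_proper × (1 − 10^(−MAPQ/10))`, the product of
annotation completeness, the properly-paired rate and the probability
that a mapping of the observed mean MAPQ is correct (MAPQ is
Phred-scaled). A `literal_formula` switch evaluates `1 − 10^MAPQ` in the
last term for auditing against sources that print the expression without
the Phred conversion; that form is negative for any positive MAPQ and is
never used for ranking. The best reference is the argmax; ties break by
higher completeness, then lexical id, so the choice is deterministic and
input-order independent.

## Synthetic data

The generators emulate a clade-wide chemical-communication study and are
the package's test bed; all are bitwise reproducible under a fixed numpy
seed.

* **Trees**: Yule (pure-birth), waiting time Exp(k·birth_rate) with k
  extant lineages; branch lengths in units of 1/birth_rate. Pure birth
  (no extinction) keeps the branch-length structure simple and is
  sufficient for exercising the covariance machinery.
* **Continuous traits**: draws from `N(μ·1, σ²C(λ))` via Cholesky.
* **Binary presence**: the two-state chain simulated branch-wise with its
  closed-form transition probabilities — this produces the patchy
  distribution of male-specific compounds across distant species.
* **Peak tables**: a common pool of shared compounds is present in both
  sexes, with per-sex log-scale abundances evolving under the sex's own
  λ (defaults 0.8 for males, 0.2 for females — strong male, weak female
  signal); sex-specific compounds get producing-species sets from the
  binary chain (gain 0.5 / loss 1.5, biased toward patchy presence) and
  are present only in the producing sex; transferred male compounds
  (probability 0.5 — the transfer fraction is a free choice, as roughly
  half of such compounds transfer in comparable systems) also appear on
  mated females of producers. Replicate noise is log-normal with CV 0.3
  (areas are positive and right-skewed); 6 replicates per species-sex
  and ~250 features per sex by default, matching the emulated design.
  The common pool is sized from the smaller sex-specific complement so
  both sexes share one feature universe.
* **Response matrices**: detection probability 0.75 for conspecific
  compounds (≈ the fraction of species detecting their own compounds in
  such panels) and 0.15 for heterospecific ones; detected responses are
  uniform on 25–125 spikes/s, non-detections uniform on [0, 10] so the
  exclusion rule is exercised exactly at its boundary — with that noise
  ceiling the network is recovered without error, which the round-trip
  tests assert.

What the generator does **not** emulate: chromatographic peak shape and
co-elution, feature-alignment errors across samples, dose-response
nonlinearity, recording noise structure, or real compound identities.
Passing tests therefore demonstrate the statistical machinery and the
calling rules, not robustness to upstream measurement artifacts.

## Problem sizes in tests

Parameter-recovery and calibration tests run at the scale that makes
their guarantees meaningful: λ recovery and the sex contrast use 100-tip
trees (200 and 2×50 traits); bootstrap calibration uses 200 datasets of
100 species with 199 bootstrap replicates (the analysis default is 2000;
199 suffices for a rejection-rate check and keeps the run proportionate).
Oracle tests (likelihood, GLS, network counts) are exact and run on small
fixed trees.

## Known limitations

* λ estimation assumes a single trait observed without measurement error;
  within-species replicate variance is averaged out, not modeled.
* The binary regression's α is selected on a fixed correlation grid, not
  by continuous optimization; resolution is adequate for bootstrap
  calibration but α̂ itself should not be over-interpreted.
* The bootstrap for nulls that retain covariates uses the latent-
  threshold approximation; its calibration is approximate where the
  intercept-only chain simulation is exact.
* PGLS assumes a fixed, error-free tree; phylogenetic uncertainty is not
  propagated.
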