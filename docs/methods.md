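# Methods

This note documents the models the package implements, the synthetic-data
generator's conditions, and the numerical choices a maintainer would want
to know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Expression components

The decomposition is a correlation-matrix PCA of a region × gene matrix:
genes are standardized across regions (sample SD, n−1), the standardized
matrix is decomposed by singular values, and loadings are scaled so each
equals the Pearson correlation between the gene and the component score.
Variance explained per component is the column sum of squared loadings
divided by the number of genes (×100); the full spectrum sums to 100%.
Regional scores are the standardized data projected on unit-norm weights
and then z-scored *within each hemisphere* (mean 0, SD 1, n−1). The
hemisphere scaling removes an additive left/right offset in mean expression
that reflects the unequal donor sampling of the two hemispheres rather than
biology; it is idempotent and is also applied to every single-gene and
cell-type profile before association testing.

Varimax rotation uses Kaiser normalization (rows scaled to unit communality
before rotation), the SVD-based pairwise criterion, convergence tolerance
1e-10, at most 1000 sweeps. Rotation is applied to the first k loading
columns and to the projection weights, so rotated scores and loadings stay
consistent; the total variance explained by the rotated k-subspace is
preserved. Component orientation is arbitrary; we canonicalize it so the
largest-magnitude loading of each component is positive.

Validation operations:

* **Partition stability** — 50 repetitions of a random 5-fold split of the
  regions; each fold in turn is the small set, the union of the rest the
  large set; unrotated components are fit on both (genes standardized
  within fold, because reusing full-sample standardization would leak the
  held-out regions into the fold), and |φ| per component index is recorded:
  250 train/test evaluations at the defaults. With ~13-region small folds
  the sampling distribution of the fold's score covariance imposes a
  ceiling on the attainable congruence of the two planted components
  (≈ E[cos θ] for the subspace mixing angle θ, plus occasional order
  swaps); the test suite therefore asserts the diagnostic *gap* — planted
  components well above the noise components — rather than an absolute
  level, which depends on the spatial statistics of the score maps.
* **Cross-model congruence** — loadings are subset to the shared genes, the
  full pairwise |φ| matrix is computed, and a best-match assignment
  maximizing total |φ| is reported (exhaustive for k ≤ 6 with lower-index
  tie-breaks, greedy otherwise), so e.g. a PC2↔PC3 correspondence between
  two pipelines is representable.

## Donor-consistency QC

For each gene, each donor's left-hemisphere regional profile is
Spearman-correlated (average ranks for ties; pairwise deletion of missing
regions) with the cross-donor median profile; genes whose mean correlation
across donors strictly exceeds 0.446 are retained. The threshold is a
published constant, kept as configuration rather than recomputed from the
region count. Right-hemisphere values inherit the left-hemisphere retention
decision. A constant donor-gene profile contributes a correlation of 0 with
a logged warning.

## Latent g (one-factor FIML CFA)

Each test is first residualized on age and sex (OLS, missingness
preserved). The measurement model is x = μ + λg + e with Var(g) = 1 for
identification (so loadings are comparable across tests), diagonal residual
variances, and optional free residual covariances between tests sharing a
named cognitive domain — the standard device for absorbing domain structure
without a second-order factor. The likelihood is the casewise multivariate
normal per missingness pattern (full information); the optimizer is
L-BFGS-B on [λ, log θ, residual covariances, μ] with an analytic gradient
(the pattern-wise ∂/∂Σ chain rule), bounds log θ ≥ log 1e-6 (Heywood cases
are floored and flagged), and up to 5 random restarts.

Fit is judged against the FIML-saturated model — closed form for complete
data, EM-estimated mean/covariance under missingness (tolerance 1e-10, max
500 iterations) — and the independence baseline (per-variable normal MLE).
χ² = 2(ll_sat − ll_model), the n·F_ML convention (an n−1 variant is
available via `chi2_denominator`). CFI, TLI, RMSEA use the standard
formulas with non-centrality floored at zero; with df = 0, RMSEA is 0 and
TLI is reported missing. SRMR is the RMS standardized covariance residual
over the lower triangle including the diagonal, computed against the
(EM) saturated covariance. Factor scores use the regression method per
pattern, λ_o'Σ_oo⁻¹(x_o − μ_o); a participant with no observed tests gets a
missing score. Score orientation is fixed by requiring a positive
correlation with a designated higher-is-better reference test.

## Regional associations and meta-analysis

Morphometry values more than 4 sample SDs from the column mean (computed
once from the full sample) are set missing. Each regional association
z-standardizes the measure and the g score on the covariate-complete
analysis sample (a deliberate choice over full-cohort standardization — it
matches the regression sample) and reports the g coefficient from OLS of
the measure on g + age + sex + head x/y/z + site dummies (+ lag where
supplied, + the whole-cortex measure when global correction is requested),
with t-based two-sided p. Whole-cortex associations (summed volume/surface
area, mean thickness) go through the same code path. Rank-deficient designs
raise an error naming the offending columns.

Pooling is DerSimonian–Laird method-of-moments (the canonical random-
effects default; the normal reference is used for p-values, configurable in
principle to t). BH-FDR is controlled within each measure's 68-region
family by default (`fdr_family="global"` pools all 204). Age moderation is
weighted least squares of cohort estimates on cohort mean age with weights
1/(SE² + τ²), τ² re-estimated by method of moments under the moderator
model and floored at zero; identical mean ages raise a collinearity error.

## Spatial inference

Spin permutations: a uniform random rotation (normalized quaternion) is
applied to the left-hemisphere unit-sphere centroids and its sagittal-plane
mirror (x → −x conjugation) to the right; a bijective original→rotated
assignment is built per hemisphere by greedy nearest-centroid matching in
random order. Each permutation preserves hemispheres and each map's value
multiset exactly. Map association forms: Pearson r (linear), Pearson r of
|map A| vs map B (absolute), and the quadratic coefficient of B ~ A + A²
(quadratic). Spin p-values permute map A only, are two-sided via
absolute-value comparison, and use the +1-corrected estimator
(1 + #{|null| ≥ |obs|})/(1 + n_perm) — never 0, never above 1. Under
strongly autocorrelated nulls the spin test rejects far less often than the
(badly anti-conservative) parametric test, though the greedy-assignment
construction is itself not exactly nominal under extreme smoothness; the
calibration experiments quantify both.

## Component-adjusted gene and cell-type mapping

A gene association is the coefficient of the z-scored, hemisphere-scaled
gene profile in OLS of the z-scored g map on gene + the two component score
maps. By Frisch–Waugh–Lovell this equals a simple regression after
residualizing on the component maps, which is how the all-genes sweep and
the spin nulls are vectorized. The spin null permutes the *gene profile*
(covariates fixed) so one shared permutation set serves every gene; this
interpretation choice is recorded in the output metadata. Profiles
correlating > .999 with a score map are flagged collinear. Candidate
selection: per-measure FDR Q < .05 → three-measure intersection → spin
p < .05 on all three, with stage sizes audited; spin p-values are computed
only for the intersection genes (each needs a full permutation sweep).
Cell-type analysis applies the same adjusted regression to the mean marker
profile of each cell type (≥ 2 genes present), with BH-FDR across the
cell-type × measure family. Loading-distribution tests use tie-corrected
Kruskal–Wallis, Dunn z-tests of each cell type against the unclassified
pool with Holm adjustment, sample skewness (g1), and kurtosis in the raw
fourth-moment (Pearson) convention by default (`excess` available); the
convention is part of the output because conventions differ across
software.

## Synthetic-data generator: what it emulates, and what it does not

The generator's defaults are the study-scale conditions.

* **Parcellation** — Fibonacci lattice on each half-sphere (x < 0 left,
  mirror-symmetric), rotated by a seed-derived angle: deterministic,
  well-spread stand-ins for FreeSurfer sphere centroids.
* **Expression** — 68 paired regions, 6 donors. Two orthogonal score maps,
  z-scaled per hemisphere, with paired left/right regions correlating ~0.85
  by construction (alternating projections reconcile the orthogonality and
  per-hemisphere scaling constraints). Bulk genes load on both components
  with Gaussian loadings at an RMS ratio ≈ 1.8:1 (echoing the observed
  31.9%/17.5% split — equal-strength components would be unidentifiable up
  to rotation); per-gene white noise is set so the components carry 50% of
  each gene's standardized variance, matching the observed two-component
  share (~49%). Truth loadings are stored on the gene–component correlation
  scale, the scale the fit recovers. A +0.056 log2 offset is added to raw
  left-hemisphere values (the observed left–right mean gap, 6.091 − 6.035);
  donor matrices add white donor noise (SD 0.1) and are summarised by the
  element-wise median.
* **Specific genes** — 10 candidate genes (nominal standardized map effect
  0.4) and a background population (25% of genes, signed effects uniform on
  [0.2, 0.7]) carry no component loading; instead each gene's profile is
  √ρ·core + √(1−ρ)·white, where the core is one shared spatial pattern
  orthogonal to both score maps and ρ converts the gene's nominal effect
  via the map's core weight. The shared core is deliberate, not incidental:
  genes that all track the same regional phenotype map cannot have mutually
  orthogonal profiles, and a background of genuinely associated genes is
  what gives BH-FDR its adaptive threshold (the real analysis found
  hundreds of per-measure FDR hits, not ten). With mutually independent
  planted profiles, each gene is irreducible residual noise for the others
  and no selection rule can reach recall 0.8 at 68 regions — the shared
  core is the generative structure under which the planted effect size is
  recoverable at all. Gene measurement noise for specific genes is folded
  into the planted correlation, so the *observed* profile correlates with
  the core at the planted strength.
* **True association maps** — per measure, on a standardized scale:
  quad_weight · z(s1² + s2²) + γ·core + white noise (variance 0.05), with
  γ² = 1 − quad_weight² − 0.05 and quad weights −0.55 / −0.50 / −0.25 for
  volume / surface area / thickness (echoing the relative strength of the
  observed component associations). Maps are then placed on the β scale
  with the observed per-measure means/SDs (0.103/0.034, 0.102/0.027,
  0.031/0.035). With no specific genes and zero noise the map is an exact
  quadratic in the true scores.
* **Cohorts** — tests are λg + within-domain shared residual (SD 0.25,
  4 domains round-robin) + unique noise at unit total variance, λ = 0.7 by
  default, plus small age/sex effects (0.1 standardized) that the
  residualization step removes; MCAR missingness on request (the simplest
  mechanism under which FIML is unbiased). Morphometry is
  β_true·g + 0.1-standardized covariate effects (age, sex, head position,
  site) + noise at unit variance. Sex is Bernoulli(0.5), age uniform over a
  cohort-specific range, sites categorical; the generative magnitudes of
  covariate effects are conventions (no empirical values exist for them)
  and are exposed in `CohortParams`.

What the generator does **not** emulate: spatial smoothness of the score
maps and morphometry maps (regions are exchangeable given the planted
structure, so spin tests on generated maps behave like permutation tests);
probe-level microarray structure, MNI sample assignment, or image volumes;
non-random missingness; cohort-specific test batteries and their cleaning
rules (kept as configuration). Passing tests therefore demonstrate the
correctness and calibration of the estimation chain under known truth, not
the spatial-autocorrelation robustness of conclusions on real cortical
maps — the conservativeness experiment addresses that separately with
explicit smooth random fields.

## Problem sizes and experiment conditions

The default end-to-end run uses 2000 genes and cohorts of 8000/1000/600
participants (the study's cohort-size ordering at package scale; the
largest cohort dominates the pooled weights) with 1000 spin permutations.
The recovery experiments use 1000-gene expression (10 seeds), 20 CFA seeds
at n = 1000, 1000 DerSimonian–Laird replicates at k = 50, 50 selection
replicates at 2000 genes, and 500/300 simulations for the spin calibration
and conservativeness checks. These sizes are the package's own defaults for
the reproduction script; all are parameters of `cogex.experiments`.

## Known limitations

* The FIML optimizer treats the saturated means as free parameters; with
  systematically missing-by-design batteries (not MCAR/MAR) estimates are
  not protected.
* The spin assignment uses greedy nearest-centroid matching; other
  published variants differ in tie handling and can shift permutation
  p-values by small amounts.
* `partition_stability` standardizes genes within fold; reusing full-sample
  standardization gives slightly higher congruence but leaks held-out
  information.
* The quadratic spatial form reports the raw quadratic coefficient, whose
  scale depends on the score map's variance; comparisons across maps should
  use the absolute-score correlation form.
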