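# Methods

This note documents the models, statistics and numerical choices behind
`olfatau`, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the design was genuinely open.

## The analysis in one paragraph

The pipeline studies how odor-identification deficits in cognitively normal
aging relate to tau accumulation and its spreading. Its stages: (1) a robust
quadratic normative curve of the 40-item odor-identification composite
(UPSIT, 0–40) against age, fit with RANSAC; (2) voxel-wise general linear
models of tau (or grey-matter, or amyloid) volumes against olfactory
predictors, with two bespoke Monte-Carlo multiple-comparison corrections;
(3) a principal-component reduction of the 40-odorant × voxel association
matrix into odorant-weight biomarkers that score subjects and project back
to the brain; (4) along-tract statistics of mean diffusivity (MD) on
skeletonized olfactory pathways divided into 100 equal segments; (5) a
directional region×region graph of tau spreading built from two-visit
regional tau via conditioned partial correlations, plus a
conditional-independence backbone (PC-algorithm skeleton) oriented by the
directional graph; and (6) co-expression clustering of smell-related genes
over a 68-region cortical parcellation with gene–trait bipartite networks.

## Mass-univariate GLM and the Z transform

All mass-univariate fits (voxels, tract segments, odorant rows) share one
vectorized OLS core. For the predictor of interest the t statistic is
converted to a signed Z by the normal quantile of the two-sided t p-value;
|Z| is capped at 37.5 (the quantile function's floating floor) with a flag,
and exact fits (numerically zero residual) are treated as t = ±∞ and
reported at the cap. Designs are checked for duplicates and rank deficiency
before any voxel is fit; collinear columns are named in the error.
Covariates enter on their native scales (binary 0/1, years); every partial
statistic downstream is scale invariant, so standardization is cosmetic and
omitted.

## Smoothness estimation and null-map construction

Residual smoothness is summarized as a Gaussian-equivalent FWHM from the
variance of first differences between neighboring in-mask voxels: under a
Gaussian autocorrelation with kernel sd s, var(diff)/var = d²/(2s²) at
spacing d, giving FWHM = 2.3548·d·sqrt(var/(2·var_diff)), averaged over axes
and subjects. Under this convention white noise has ≈1.18 voxels of
equivalent FWHM and kernel smoothing adds approximately in quadrature.

Null maps for the Monte-Carlo corrections are white noise smoothed with the
kernel whose *estimated* FWHM equals the target: the estimator is inverted
exactly through the lag-1 autocorrelation of the discrete kernel (bisection
per axis). Two details matter for calibration and were validated on
pure-noise simulations:

* null maps are normalized by the exact per-voxel sd of the smoothing
  operator (separable per-axis row norms, reflect boundaries) rather than by
  each map's empirical sd — empirical standardization suppresses genuine
  map-level variance fluctuations and shrinks null cluster sizes, making the
  correction anti-conservative;
* a target FWHM at or below the voxel size applies no kernel, so the
  "unsmoothed" count null is exactly i.i.d. per voxel and reproduces the
  Binomial(40, α) per-voxel count law (total-variation distance ≈ 1e-3 at
  5000 iterations — the oracle check in the acceptance suite).

The cluster correction thresholds a map at two-sided voxel p (default 0.05),
labels suprathreshold voxels (26-neighborhood default; 6 available), and
refers each observed cluster size to the distribution of the maximum null
cluster size; cluster p = (1 + #null ≥ size)/(n_iter + 1), flagged when no
null maximum reached the size. The odorant-count correction repeats 40
independent null maps per iteration and takes the smallest per-voxel count
whose family-wise probability (via the max-count distribution over the mask)
falls below 0.05. On 200 pure-noise datasets (20³ mask, n = 60, 1000-
iteration nulls) both corrections hold the family-wise error at ≈5%
(cluster ≈ 0.05 pooled over seeds, count ≈ 0.01 — the count threshold is
conservative because the 40 real odorant maps are slightly positively
correlated while the null maps are independent). In that calibration
experiment the null distributions are computed once from the first
replicate's estimated smoothness and reused, since the replicates are
i.i.d. with identical masks.

## RANSAC normative curve

5000 iterations of least-squares quadratic fits on random 20-subject
subsets; inliers are subjects within 6 composite points of the prediction;
the consensus model maximizes the inlier count (ties to the first iteration
under the seeded RNG; singular subset fits are skipped and counted). The
returned coefficients are refit on the consensus inlier set and the inlier
mask recomputed under the final model, keeping the two consistent — refit is
standard RANSAC practice and stabilizes the coefficients; the
best-minimal-sample model is available with `refit=False`. The threshold is
applied to the absolute residual (symmetric band).

## Odorant biomarkers

The association matrix stacks, per odorant, the Z map of the GLM with that
odorant's binary identification as predictor (equivalent to a covariate-
adjusted two-group comparison), tau block then amyloid block (the
longitudinal variant uses follow-up−baseline tau voxels only). PCA runs over
the odorant dimension after centering each voxel column across odorants; no
voxel scaling is applied because Z values are already variance stabilized.
Missing odorant rows (items identified by everyone or no one) are
mean-imputed — zero after centering — and flagged. Components are
sign-flipped so the largest-|weight| odorant is positive. Subject scores are
the weighted sum of (by default centered) binary responses; back-projection
delegates to the voxel GLM with the score as predictor and supports
adjusting for the other modality's global value.

## Along-tract statistics

The tract centerline is the shortest path through the 26-connected voxel
graph of the mask between the endpoints (edge weights = physical step
lengths), smoothed with a symmetric moving average and resampled at 2000
equal-arc-length points; the 100 segments are equal arc-length bins, and
every mask voxel joins the segment of its nearest centerline sample. The
centerline is computed once per unordered endpoint pair in a canonical
orientation, so swapping source and target reverses profiles exactly.
Per-segment mean MD feeds the shared GLM core; empty segments are missing
(the default phantom's 6 mm tube radius keeps all 100 segments populated on
a 2 mm grid), and a fit is refused when more than half the segments are
missing. No multiple-comparison correction is applied across the 100
segments by default (per-segment significance is reported for the line
plot); FDR is available downstream of the returned p-values.

## Directional spreading graph and backbone

For each ordered region pair (i, j), the edge statistic is the partial
correlation of baseline tau at i with follow-up tau at j conditioned on
baseline tau at j plus the configured covariates (age, sex, APOE ε4,
smoking, inter-scan interval by default). Conditioning on the target's own
baseline makes the association reflect longitudinal accumulation rather
than cross-sectional covariance; under linearity it is equivalent to
modeling change. Partial correlations are computed from the precision
matrix of the involved variables; the residualize-then-correlate identity
is kept as an independent oracle in the test suite (agreement to 1e-10).
Degenerate pairs (constant regions, or follow-up identical to baseline,
which leaves a zero conditioned residual) are reported missing with a flag
rather than as spurious zeros. Edges are thresholded at p < 0.05
(uncorrected, by design); weighted in/out degrees sum |r| over significant
edges.

The backbone is the skeleton phase of the PC algorithm on baseline values:
growing conditioning-set sizes ℓ = 0, 1, …, Fisher-z independence tests at
α, neighbor subsets enumerated lexicographically over sorted names for
determinism, separating sets recorded on first independence. The sample
must satisfy n − ℓ − 3 ≥ 1 or the requested ℓ is refused with the limit
named. No v-structure or Meek orientation is applied; arrows are copied
from the directional graph (forward-only significance ⇒ arrow, both ⇒
bidirectional, neither ⇒ undirected). A dorsal-raphe MD value can enter as
a baseline-side node only.

## Gene co-expression

Samples are averaged per donor and region, the cross-donor median taken,
and each gene z-scored across regions (in that order). Pearson
co-expression feeds agglomerative clustering on distance 1 − r with average
linkage (complete/ward available); k is chosen by maximum mean silhouette
over the examined range, ties to the smallest k. Cluster mean-expression
maps are re-z-scored separately per hemisphere. The gene–trait network
keeps catalog rows with p < 1e-5 (the catalog inclusion bound; weaker rows
are filtered and counted), maps traits into six neurodegeneration domains,
and weights every edge by the best (minimum) p, with the gene–domain
reduction again taking the minimum over member traits.

## What the generators emulate — and what they do not

`synthetic_data` plants known structure at the emulated study's scales:

* **Cohort** (default n = 418, ages 55–90): composite scores target a
  quadratic age trend (default peak ≈36 points near age 55, ≈24 at 90)
  with 2 points of Gaussian dispersion; a configurable fraction of gross
  outliers is shifted −15 points. Under the default "competition" response
  model the identified items are the target-count items with the highest
  difficulty-plus-Gumbel utilities, so the composite matches its target
  exactly (and equals the rounded trend in the zero-noise limit); the
  "independent" model draws items conditionally independent given age with
  probabilities calibrated so their sum matches the target. Covariates are
  sex/APOE ε4/smoking as 0/1, education in years, inter-scan interval
  2.38 ± 0.45 years.
* **Regional tau** (8 olfactory/medial-temporal regions): baseline
  1.2 ± 0.15 SUVr i.i.d.; follow-up adds β·baseline_source·Δt for each
  planted directed edge (default β = 0.05/yr from three medial-temporal →
  olfactory edges) plus 0.02 SUVr noise. At n = 89 the planted partial
  correlations are ≈0.6–0.7, a clearly detectable regime.
* **Tract phantom**: a ~70 mm curved 6 mm-radius tube on a 2 mm grid;
  MD 0.8e-3 mm²/s baseline, 5e-5 voxel noise, and 1e-5 mm²/s per composite
  point on the effect segments — chosen so the planted along-tract effect is
  unambiguous at n = 82 while the null segments stay calibrated.
* **Expression**: k equal clusters sharing a regional factor with
  within-cluster correlation w (default 0.8), 68 regions split L/R, with
  optional per-cluster hemisphere shifts.
* **Biomarker fixture**: a latent severity trait s ~ N(0,1) drives both the
  odorant responses (logistic items with slopes 6·u_k along the planted
  unit weight vector — item–trait correlations ≈0.3–0.5, the strongly
  trait-determined regime where a composite biomarker is meaningful) and
  voxel tau (pattern × s, 0.15 effect vs 0.1 noise). The ground-truth
  loading profile is the population item–trait correlation vector computed
  by Gauss–Hermite quadrature. Planting severity as a linear function of
  the measured responses instead has a hard recovery ceiling
  (cos ≈ 0.89 at n = 150 with 40 items, from sampling noise of the
  item–severity correlations shared across voxels) and was rejected as a
  fixture on those grounds.

Not emulated: PET physics and off-target binding, scanner noise spectra,
partial-volume effects, anatomical realism, tractography, probe-level
transcriptome preprocessing, and any correlation between odorant responses
beyond the mechanisms above. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure at realistic sizes and
stays calibrated on noise — not that real acquisitions meet the model's
assumptions.

## Problem sizes

The validation experiments use 20³-voxel masks (n = 60) for the Monte-Carlo
calibrations at 1000 null iterations, 100 simulations for the tract and
spreading-graph recoveries, 50 seeds for the PC-chain and expression
recoveries, and 5000 iterations for the binomial count-null oracle; the
demo pipeline runs a 120-subject cohort with 60 imaging subjects on a 20³
grid with 300-iteration nulls. These sizes give Monte-Carlo error well
inside every stated tolerance while keeping a full run in the minutes
range; the full-scale defaults (5000/10000 iterations, 24³ grids) are the
package defaults outside the validation suite.

## Known limitations

* The map-level Gaussian null approximates the spatial behavior of
  t-derived Z maps; the residual-sd field of a t map adds scale mixing the
  null does not model. On the calibration grid the effect is within
  Monte-Carlo error of nominal, but very low degrees of freedom could
  expose it.
* The smoothness estimator assumes stationary Gaussian autocorrelation;
  strongly anisotropic or non-stationary residuals are summarized by a
  single averaged FWHM.
* PC-skeleton output at finite n depends on α and test order only through
  the documented deterministic enumeration; it equals exhaustive
  all-subsets testing on the tested ≤5-node fixtures but can diverge from
  it on unfaithful or weak-signal data.
* The silhouette criterion cannot select k = 1; a single-cluster structure
  reports its (low) silhouette across the examined range instead.
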