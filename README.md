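# olfatau

Analysis pipeline for studying how odor-identification deficits in
cognitively normal aging relate to tau accumulation and its directional
spreading through the olfactory and medial temporal systems — with a
first-class synthetic-data module so every stage is testable end-to-end
against planted ground truth.

It is aimed at neuroimaging researchers working with olfactory testing
(40-item odor-identification composites, 0–40), longitudinal tau/amyloid
PET volumes, diffusion MRI tract masks, and regional transcriptome data.
The real cohorts such analyses run on are access-restricted, so the package
ships generators that emulate their statistical structure at realistic
sizes.

## What it computes

* **Normative aging curve** (`aging_norms`): RANSAC-robust quadratic fit of
  composite score vs age (5000 iterations of 20-subject subsets, 6-point
  inlier band), per-subject deviations from the norm, per-odorant
  identification rates.
* **Voxel-wise association mapping** (`voxel_assoc`): vectorized per-voxel
  GLMs with signed-Z output; residual smoothness estimation; a
  Monte-Carlo *odorant-count* null (how many of 40 per-odorant tests a
  voxel passes by chance, family-wise over the mask) and cluster-wise
  Monte-Carlo correction against smoothness-matched Gaussian null maps.
* **Odorant biomarkers** (`odorant_biomarker`): PCA of the 40-odorant ×
  (tau + amyloid) voxel Z-association matrix; odorant-weight components,
  per-subject dysfunction scores, back-projection to corrected brain maps.
* **Along-tract statistics** (`tract_stats`): shortest-path skeletonization
  of a tract mask, 100 equal-arc-length segments, nearest-segment voxel
  assignment, per-segment GLM of mean diffusivity vs odor identification.
* **Directional spreading graph** (`spread_graph`): for every ordered
  region pair, the partial correlation of baseline tau at the source with
  follow-up tau at the target, conditioned on the target's baseline plus
  covariates — an asymmetric graph whose in/out degrees quantify tau
  "receiving" and "sending"; plus the PC-algorithm skeleton on baseline
  values with arrows copied from the directional graph.
* **Gene co-expression** (`gene_coexpr`): donor-median, z-scored
  genes × regions expression; Pearson co-expression; agglomerative
  clustering with silhouette-selected k; per-hemisphere z-scored cluster
  maps; gene–trait bipartite networks weighted by best GWAS p-value.
* **Orchestration** (`pipeline`, `olfatau` CLI): a single YAML config runs
  simulate → norms → voxelwise → biomarker → tracts → graph → genes with a
  JSON manifest per run.

The central spreading statistic: for regions i ≠ j,

    edge(i → j) = parcorr( tau_i(t0), tau_j(t1) | tau_j(t0), age, sex, APOEε4, smoking, Δt )

so an edge reflects the association of baseline tau at the source with
longitudinal accumulation at the target, not cross-sectional covariance.

## Worked example

```python
import numpy as np
from olfatau import CohortSpec, SpreadTruth, generate_cohort, generate_regional_tau
from olfatau.aging_norms import fit_ransac_quadratic
from olfatau.spread_graph import tau_connectivity, node_degrees

cohort = generate_cohort(CohortSpec(n_subjects=418, outlier_fraction=0.05, seed=42))
fit = fit_ransac_quadratic(cohort["age"], cohort["upsit"], seed=42)
print(f"quadratic coefficients: {np.round(fit.coeffs, 4)}")
print(f"inliers: {fit.n_inliers}/{len(cohort)}")

panel = generate_regional_tau(cohort.iloc[:89], SpreadTruth(seed=42))
g = tau_connectivity(panel, covariates=cohort.iloc[:89][["age", "sex", "apoe4", "smoking", "interval"]])
adj = g.adjacency()
for src in g.regions:
    for dst in g.regions:
        if src != dst and adj.loc[src, dst] and abs(g.r.loc[src, dst]) > 0.3:
            print(f"  {src} -> {dst}: r = {g.r.loc[src, dst]:.2f}")
print(node_degrees(g).round(2).loc[["Amyg", "Ent", "Parahipp"]])
```

prints

```
quadratic coefficients: [ 4.4646  1.121  -0.0101]
inliers: 396/418
  Ent -> AON: r = 0.61
  Amyg -> PirF: r = 0.74
  Parahipp -> TUR: r = 0.64
          out_degree  in_degree
Amyg            0.74        0.5
Ent             0.61        0.0
Parahipp        0.89        0.0
```

The cohort was generated with a quadratic age trend of (5.75, 1.1, −0.01)
and 5% of subjects shifted −15 points: the robust fit recovers the curve
(the refit intercept absorbs part of the small age² difference; the
predicted curve deviates by <0.5 points across the age range) and excludes
the planted outliers (396 inliers ≈ 95% of 418). The spreading panel was
generated with exactly three directed transfer edges (amygdala → frontal
piriform, entorhinal → anterior olfactory nucleus, parahippocampus →
olfactory tubercle); the conditioned graph recovers all three, none in
reverse, and the degree table shows the three medial temporal regions as
pure senders (out-degree > 0, in-degree ≈ 0 — amygdala's in-degree here
comes from a coincidental secondary association).

Run the full synthetic study from the command line:

```bash
olfatau run-all --demo --seed 1 --out runs/demo   # minutes-scale demo
olfatau stages                                     # list stage order
```

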