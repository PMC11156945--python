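"""End-to-end recovery and calibration experiments on synthetic ground truth.

Each function simulates data under the documented study conditions (cohort
sizes and noise levels mirroring the 418 / 155 / 89 / 82-subject samples of
the emulated design, at grid sizes small enough for a laptop), runs the
corresponding pipeline stage, and returns summary metrics. These experiments
double as the package's acceptance checks and as worked examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from . import aging_norms, gene_coexpr, odorant_biomarker, spread_graph, tract_stats, voxel_assoc
from .imaging_io import ODORANT_COLUMNS, VolumeSet, build_design
from .synthetic_data import (
    CohortSpec,
    ExpressionTruth,
    SpreadTruth,
    TractPhantomSpec,
    generate_cohort,
    generate_expression,
    generate_regional_tau,
    generate_tract_md,
    substream,
)

GLM_COVARIATES = ("age", "sex", "apoe4", "smoking")


# ---------------------------------------------------------------------------
# Normative curve recovery
# ---------------------------------------------------------------------------

def ransac_recovery(seed: int = 0, n_subjects: int = 400, outlier_fraction: float = 0.05):
    """Recover the quadratic aging curve from a cohort with planted outliers.

    Returns the maximum |fitted - generating| curve error over the age range
    (UPSIT points) and the fraction of planted outliers classified outliers.
    """
    spec = CohortSpec(
        n_subjects=n_subjects,
        outlier_fraction=outlier_fraction,
        score_noise_sd=2.0,
        outlier_shift=-15.0,
        seed=seed,
    )
    cohort = generate_cohort(spec)
    fit = aging_norms.fit_ransac_quadratic(
        cohort["age"], cohort["upsit"], n_iter=5000, sample_size=20, threshold=6.0, seed=seed
    )
    grid = np.linspace(*spec.age_range, 200)
    a0, a1, a2 = spec.quadratic_coeffs
    truth_curve = a0 + a1 * grid + a2 * grid**2
    max_err = float(np.max(np.abs(fit.predict(grid) - truth_curve)))
    planted = cohort["is_outlier"].to_numpy()
    detected = float((~fit.inlier_mask[planted]).mean()) if planted.any() else np.nan
    return {
        "max_curve_error": max_err,
        "outlier_detection_rate": detected,
        "n_inliers": fit.n_inliers,
        "n": n_subjects,
    }


# ---------------------------------------------------------------------------
# Monte-Carlo family-wise calibration on pure noise
# ---------------------------------------------------------------------------

def _noise_volumes(rng, n_subjects, shape, smooth_sigma):
    from scipy.ndimage import gaussian_filter

    data = rng.standard_normal((n_subjects, *shape))
    if smooth_sigma > 0:
        data = gaussian_filter(data, sigma=(0, smooth_sigma, smooth_sigma, smooth_sigma))
    return data


def fwe_calibration(
    seed: int = 0,
    n_datasets: int = 200,
    shape=(20, 20, 20),
    n_subjects: int = 60,
    n_iter: int = 1000,
    alpha: float = 0.05,
    smooth_sigma: float = 0.85,
):
    """Family-wise error of the cluster and odorant-count corrections.

    ``n_datasets`` pure-noise datasets (subject volumes = smoothed white
    noise, independent of every predictor) are each analyzed with (a) the
    cluster-wise correction of the composite-score map and (b) the
    odorant-count map with its Monte-Carlo threshold. The null distributions
    depend only on the mask and residual smoothness, which are identical
    across the i.i.d. replicates, so they are computed once from the first
    dataset and reused. Returns the fractions of datasets with any
    significant cluster / any flagged voxel (both nominally <= alpha).
    """
    rng = substream(seed, "fwe_calibration")
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects, seed=seed))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    mask = np.ones(shape, bool)
    designs = [build_design(cohort, predictor="upsit", covariates=GLM_COVARIATES)]
    odorant_designs = []
    for col in ODORANT_COLUMNS:
        resp = cohort[col].to_numpy()
        if resp.min() == resp.max():
            odorant_designs.append(None)
        else:
            odorant_designs.append(build_design(cohort, predictor=col, covariates=GLM_COVARIATES))

    null_max_sizes = None
    count_null = None
    cluster_hits = 0
    count_hits = 0
    for d in range(n_datasets):
        vol = VolumeSet(
            data=_noise_volumes(rng, n_subjects, shape, smooth_sigma), affine=affine, mask=mask
        )
        smap = voxel_assoc.fit_voxel_glm(vol, designs[0])
        if null_max_sizes is None:
            resid = voxel_assoc.glm_residuals(vol, designs[0])
            fwhm = voxel_assoc.estimate_smoothness(resid)
            zcrit = stats.norm.isf(alpha / 2.0)
            null_max_sizes = voxel_assoc.simulate_null_max_sizes(
                mask, vol.voxel_sizes, fwhm, zcrit, n_iter, seed=int(rng.integers(2**31))
            )
            count_null = voxel_assoc.odorant_count_null(
                mask, vol.voxel_sizes, fwhm,
                n_iter=n_iter, n_maps=40, alpha=alpha,
                seed=int(rng.integers(2**31)),
            )
        res = voxel_assoc.cluster_correct(
            smap, fwhm_est=fwhm, voxel_p=alpha, null_max_sizes=null_max_sizes
        )
        if len(res.significant(alpha)):
            cluster_hits += 1
        maps = [
            voxel_assoc.fit_voxel_glm(vol, dz) if dz is not None else None
            for dz in odorant_designs
        ]
        cmap = voxel_assoc.count_map(maps, count_null.threshold_count, alpha=alpha)
        if cmap.flagged.any():
            count_hits += 1
    return {
        "cluster_fwe_rate": cluster_hits / n_datasets,
        "count_fwe_rate": count_hits / n_datasets,
        "threshold_count": count_null.threshold_count,
        "fwhm_est": fwhm,
        "n": n_datasets,
    }


def count_null_binomial_tv(seed: int = 0, shape=(8, 8, 8), n_iter: int = 5000):
    """Total-variation distance of the unsmoothed count null to Binomial(40, .05).

    With the target smoothness at the voxel size no kernel is applied, voxels
    are i.i.d., and the per-voxel count of significant maps is exactly
    Binomial(n_maps, alpha).
    """
    mask = np.ones(shape, bool)
    null = voxel_assoc.odorant_count_null(
        mask, (2.0, 2.0, 2.0), fwhm_est=2.0, n_iter=n_iter, n_maps=40, alpha=0.05, seed=seed
    )
    emp = null.count_histogram / null.count_histogram.sum()
    theo = stats.binom.pmf(np.arange(41), 40, 0.05)
    tv = 0.5 * float(np.abs(emp - theo).sum())
    return {"tv_distance": tv, "threshold_count": null.threshold_count, "n": n_iter}


# ---------------------------------------------------------------------------
# Biomarker recovery
# ---------------------------------------------------------------------------

def planted_weight_vector(rng) -> np.ndarray:
    """Zero-mean unit-norm odorant weight vector (a contrast of odorants)."""
    w = rng.normal(size=40)
    w -= w.mean()
    return w / np.linalg.norm(w)


def _item_trait_profile(intercepts: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """Population corr(response_k, trait) for Bernoulli(sigmoid(b_k + a_k s)).

    Gauss-Hermite quadrature over the standard-normal trait s.
    """
    from scipy.special import roots_hermitenorm

    nodes, weights = roots_hermitenorm(61)
    weights = weights / weights.sum()
    p = 1.0 / (1.0 + np.exp(-(intercepts[:, None] + slopes[:, None] * nodes[None, :])))
    ep = p @ weights
    cov = (p * nodes[None, :]) @ weights
    var = ep * (1 - ep)
    return cov / np.sqrt(np.maximum(var, 1e-12))


def biomarker_recovery(
    seed: int = 0,
    n_subjects: int = 150,
    n_voxels: int = 500,
    trait_strength: float = 6.0,
    effect: float = 0.15,
    noise_sd: float = 0.1,
):
    """Rank-1 planted odorant-weight simulation.

    A latent per-subject dysfunction severity s ~ N(0,1) drives both the
    odorant responses (item k is Bernoulli with logit b_k + trait_strength *
    u_k * s, u the planted unit weight vector) and tau (every voxel is a
    spatial pattern times s plus noise), so the odorant-association matrix is
    rank 1 with loading direction equal to the population item-trait
    correlation profile. Recovery: cosine of the first component's loadings
    with that profile, and correlation of subject scores with s. The default
    trait strength puts item-trait correlations around 0.3-0.5 — the
    strongly-determined regime where a composite olfactory biomarker is
    meaningful.
    """
    rng = substream(seed, "biomarker")
    cohort = generate_cohort(CohortSpec(n_subjects=n_subjects, seed=seed))
    u = planted_weight_vector(rng)
    d = np.linspace(0.05, 0.55, 40)
    intercepts = np.log((1 - d) / d)
    slopes = trait_strength * u
    severity = rng.normal(size=n_subjects)
    logits = intercepts[None, :] + slopes[None, :] * severity[:, None]
    resp = (rng.random((n_subjects, 40)) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    cohort = cohort.copy()
    cohort[ODORANT_COLUMNS] = resp
    cohort["upsit"] = resp.sum(axis=1)
    rho = _item_trait_profile(intercepts, slopes)
    rho_dir = rho / np.linalg.norm(rho)
    pattern = rng.normal(size=n_voxels)
    shape = (10, 10, n_voxels // 100)
    tau = 1.2 + effect * severity[:, None] * pattern[None, :] + rng.normal(
        0, noise_sd, size=(n_subjects, n_voxels)
    )
    vol = VolumeSet(
        data=tau.reshape(n_subjects, *shape),
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        mask=np.ones(shape, bool),
    )
    M = odorant_biomarker.build_assoc_matrix(cohort, {"tau": vol}, covariates=GLM_COVARIATES)
    comps = odorant_biomarker.pca_components(M, n_components=3)
    w_est = comps[0].weights
    cosine = float(np.abs(w_est @ rho_dir))
    score = odorant_biomarker.score_subjects(comps[0], cohort)
    corr = float(np.abs(np.corrcoef(score.scores, severity)[0, 1]))
    return {
        "loading_cosine": cosine,
        "score_severity_corr": corr,
        "variance_explained": comps[0].variance_explained,
        "n": n_subjects,
    }


# ---------------------------------------------------------------------------
# Along-tract recovery
# ---------------------------------------------------------------------------

def tract_recovery(
    seed: int = 0,
    n_sims: int = 100,
    n_subjects: int = 82,
    effect_segments=tuple(range(40, 61)),
):
    """Tube-phantom along-tract power and per-segment false-positive rate.

    Per simulation a fresh cohort and phantom noise are drawn; with the
    planted effect the argmax |T| segment is recorded, and with zero effect
    the per-segment p < .05 rate is pooled.
    """
    rng = substream(seed, "tract")
    base_spec = TractPhantomSpec(effect_segments=effect_segments, seed=seed)
    cohort0 = generate_cohort(CohortSpec(n_subjects=n_subjects, seed=seed))
    mask0, _ = generate_tract_md(cohort0, base_spec)
    skel = tract_stats.skeletonize(
        mask0.mask, mask0.affine, mask0.source_point, mask0.target_point,
        n_segments=base_spec.n_segments,
    )
    hits = 0
    fp = []
    for s in range(n_sims):
        sim_seed = int(rng.integers(2**31))
        cohort = generate_cohort(CohortSpec(n_subjects=n_subjects, seed=sim_seed))
        spec_eff = TractPhantomSpec(effect_segments=effect_segments, seed=sim_seed)
        _, md = generate_tract_md(cohort, spec_eff)
        prof = tract_stats.segment_profiles(skel, md)
        res = tract_stats.along_tract_glm(prof, cohort)
        arg = int(np.nanargmax(np.abs(res.t))) + 1
        if 35 <= arg <= 65:
            hits += 1
        spec_null = TractPhantomSpec(effect_segments=(), effect_size=0.0, seed=sim_seed)
        _, md0 = generate_tract_md(cohort, spec_null)
        res0 = tract_stats.along_tract_glm(tract_stats.segment_profiles(skel, md0), cohort)
        fp.append(res0.p[~np.isnan(res0.p)] < 0.05)
    return {
        "argmax_hit_rate": hits / n_sims,
        "false_positive_rate": float(np.nanmean(np.concatenate(fp))),
        "n": n_sims,
    }


# ---------------------------------------------------------------------------
# Spreading-graph recovery
# ---------------------------------------------------------------------------

def spread_recovery(seed: int = 0, n_sims: int = 100, n_subjects: int = 89):
    """Directed-edge recovery of the planted spreading structure.

    Pools |r| scores over all ordered region pairs and simulations for the
    ROC AUC against planted-edge labels, and counts, per planted edge and
    simulation, whether the forward direction is significant while the
    reverse is not.
    """
    rng = substream(seed, "spread")
    scores, labels = [], []
    asym = []
    covariate_cols = list(spread_graph.DEFAULT_GRAPH_COVARIATES)
    for s in range(n_sims):
        sim_seed = int(rng.integers(2**31))
        cohort = generate_cohort(CohortSpec(n_subjects=n_subjects, seed=sim_seed))
        truth = SpreadTruth(seed=sim_seed)
        panel = generate_regional_tau(cohort, truth)
        g = spread_graph.tau_connectivity(panel, covariates=cohort[covariate_cols])
        planted = {(a, b) for a, b, _ in truth.edges}
        for i in g.regions:
            for j in g.regions:
                if i == j:
                    continue
                scores.append(abs(g.r.loc[i, j]))
                labels.append((i, j) in planted)
        for a, b, _ in truth.edges:
            asym.append(g.has_edge(a, b) and not g.has_edge(b, a))
    return {
        "edge_auc": float(roc_auc_score(labels, scores)),
        "direction_asymmetry_rate": float(np.mean(asym)),
        "n": n_sims,
    }


# ---------------------------------------------------------------------------
# PC-skeleton oracles
# ---------------------------------------------------------------------------

def _simulate_sem(edges, nodes, n, rng, beta=0.9):
    """Linear-Gaussian structural equations in topological (list) order."""
    data = {}
    for v in nodes:
        parents = [a for a, b in edges if b == v]
        x = rng.normal(size=n)
        for p in parents:
            x = x + beta * data[p]
        data[v] = x
    return pd.DataFrame(data)


def brute_force_skeleton(data: pd.DataFrame, alpha: float = 0.05):
    """Independent oracle: test every pair against all subsets of all others."""
    import itertools

    nodes = list(data.columns)
    n = len(data)
    edges = set()
    for x, y in itertools.combinations(nodes, 2):
        rest = [v for v in nodes if v not in (x, y)]
        independent = False
        for ell in range(len(rest) + 1):
            for S in itertools.combinations(rest, ell):
                Z = np.column_stack([data[s] for s in S]) if S else None
                r = spread_graph.partial_corr(data[x].to_numpy(), data[y].to_numpy(), Z)
                if spread_graph.fisher_z_pvalue(r, n, ell) > alpha:
                    independent = True
                    break
            if independent:
                break
        if not independent:
            edges.add(frozenset((x, y)))
    return edges


SEM_FIXTURES = {
    "independent_pair": ([], ["A", "B"]),
    "chain3": ([("A", "B"), ("B", "C")], ["A", "B", "C"]),
    "collider": ([("A", "C"), ("B", "C")], ["A", "B", "C"]),
    "fork": ([("B", "A"), ("B", "C")], ["B", "A", "C"]),
    "diamond": ([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")], ["A", "B", "C", "D"]),
    "chain5": (
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")],
        ["A", "B", "C", "D", "E"],
    ),
}


def pc_oracle(seed: int = 0, n: int = 500, alpha: float = 0.05):
    """pc_skeleton vs the exhaustive all-subsets oracle on <=5-node SEMs."""
    rng = substream(seed, "pc_oracle")
    agree = {}
    for name, (edges, nodes) in SEM_FIXTURES.items():
        data = _simulate_sem(edges, nodes, n, rng)
        skel = spread_graph.pc_skeleton(data, alpha=alpha)
        brute = brute_force_skeleton(data, alpha=alpha)
        agree[name] = skel.edges == brute
    return {"agreement_rate": float(np.mean(list(agree.values()))), "per_fixture": agree, "n": n}


def chain_separation(seed: int = 0, n_seeds: int = 50, n: int = 500):
    """A-B-C chain: rate at which A-C is removed with separating set {B}."""
    rng = substream(seed, "pc_chain")
    ok = 0
    for _ in range(n_seeds):
        data = _simulate_sem([("A", "B"), ("B", "C")], ["A", "B", "C"], n, rng)
        skel = spread_graph.pc_skeleton(data, alpha=0.05)
        e = frozenset(("A", "C"))
        if (
            e not in skel.edges
            and skel.separating_sets.get(e) == ("B",)
            and skel.has_edge("A", "B")
            and skel.has_edge("B", "C")
        ):
            ok += 1
    return {"chain_recovery_rate": ok / n_seeds, "n": n_seeds}


def partial_corr_oracle(seed: int = 0, n_panels: int = 100):
    """Precision-matrix route vs residualize-then-correlate on random panels."""
    rng = substream(seed, "pcorr_oracle")
    max_err = 0.0
    for _ in range(n_panels):
        n = int(rng.integers(40, 120))
        k = int(rng.integers(0, 4))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.3 * x
        Z = rng.normal(size=(n, k)) if k else None
        if Z is not None:
            y = y + Z @ rng.normal(size=k)
        r = spread_graph.partial_corr(x, y, Z)
        # oracle: regress both on [1, Z], correlate the residuals
        X = np.column_stack([np.ones(n)] + ([Z] if Z is not None else []))
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        max_err = max(max_err, abs(r - r_oracle))
    return {"max_abs_error": float(max_err), "n": n_panels}


# ---------------------------------------------------------------------------
# Expression-clustering recovery
# ---------------------------------------------------------------------------

def expression_recovery(
    seed: int = 0, n_seeds: int = 50, n_genes: int = 200, k: int = 4, corr: float = 0.8
):
    """Silhouette-selected k and adjusted agreement with planted clusters."""
    rng = substream(seed, "expression_recovery")
    ok = 0
    aris = []
    for _ in range(n_seeds):
        truth = ExpressionTruth(
            n_genes=n_genes, k_clusters=k, within_cluster_corr=corr,
            seed=int(rng.integers(2**31)),
        )
        expr = generate_expression(truth)
        cx = gene_coexpr.coexpression(expr)
        clusters = gene_coexpr.cluster_genes(cx, k_range=range(2, 9))
        ari = adjusted_rand_score(expr.truth_labels, clusters.labels.to_numpy())
        aris.append(ari)
        if clusters.k == k and ari >= 0.9:
            ok += 1
    return {"recovery_rate": ok / n_seeds, "mean_ari": float(np.mean(aris)), "n": n_seeds}
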