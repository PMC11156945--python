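"""End-to-end orchestration of the synthetic study from a single config.

``run_all`` executes the stages in dependency order (simulate -> norms ->
voxelwise -> biomarker -> tracts -> graph -> genes), writing each stage's
outputs and a manifest into the run directory. Stages read their inputs from
the run directory, so individual stages can be rerun; a failing stage leaves
prior outputs intact and is marked in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aging_norms, gene_coexpr, odorant_biomarker, spread_graph, tract_stats, voxel_assoc
from .exceptions import MissingInputError, OlfatauError
from .imaging_io import ODORANT_COLUMNS, VolumeSet, build_design, write_map
from .synthetic_data import (
    CohortSpec,
    ExpressionTruth,
    RegionalTauPanel,
    SpreadTruth,
    TractPhantomSpec,
    generate_cohort,
    generate_expression,
    generate_regional_tau,
    generate_tract_md,
    make_synthetic_atlas,
    paint_volumes,
    substream,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "norms", "voxelwise", "biomarker", "tracts", "graph", "genes")


@dataclass
class RunConfig:
    """Serializable run configuration; defaults mirror the full analysis.

    Iteration counts default to the full-scale settings (RANSAC 5000 subsets
    of 20 with a 6-point band; 5000-iteration 40-map count null; 10000-
    iteration cluster null); demo configs override them explicitly.
    """

    seed: int = 0
    cohort: dict = field(default_factory=lambda: {"n_subjects": 418, "outlier_fraction": 0.03})
    imaging_n_subjects: int = 155
    atlas: dict = field(default_factory=lambda: {"shape": [24, 24, 24], "voxel_size": 2.0})
    paint: dict = field(default_factory=lambda: {"smoothing_fwhm": 4.0, "voxel_noise_sd": 0.05})
    ransac: dict = field(default_factory=lambda: {"n_iter": 5000, "sample_size": 20, "threshold": 6.0})
    covariates: list = field(default_factory=lambda: ["age", "sex", "apoe4", "smoking"])
    graph_covariates: list = field(default_factory=lambda: ["age", "sex", "apoe4", "smoking", "interval"])
    alpha: float = 0.05
    count_null: dict = field(default_factory=lambda: {"n_iter": 5000, "n_maps": 40})
    cluster: dict = field(default_factory=lambda: {"n_iter": 10000, "voxel_p": 0.05})
    n_components: int = 3
    spread: dict = field(default_factory=dict)
    tract: dict = field(default_factory=dict)
    expression: dict = field(default_factory=lambda: {"n_genes": 200, "k_clusters": 4, "within_cluster_corr": 0.8})
    pc: dict = field(default_factory=lambda: {"alpha": 0.05, "max_cond": 3})
    gene_k_range: list = field(default_factory=lambda: [2, 8])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise OlfatauError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config(seed: int = 0) -> RunConfig:
    """Reduced-size configuration that runs end-to-end in minutes."""
    return RunConfig(
        seed=seed,
        cohort={"n_subjects": 120, "outlier_fraction": 0.03},
        imaging_n_subjects=60,
        atlas={"shape": [20, 20, 20], "voxel_size": 2.0},
        ransac={"n_iter": 2000, "sample_size": 20, "threshold": 6.0},
        count_null={"n_iter": 300, "n_maps": 40},
        cluster={"n_iter": 300, "voxel_p": 0.05},
        expression={"n_genes": 120, "k_clusters": 4, "within_cluster_corr": 0.8},
    )


class Manifest:
    """Stage ledger persisted as JSON after every stage."""

    def __init__(self, rundir: Path, config: RunConfig):
        self.path = Path(rundir) / "manifest.json"
        self.data = {
            "package_version": __version__,
            "config_hash": config.hash(),
            "seed": config.seed,
            "stages": {},
        }

    def record(self, stage: str, status: str, outputs=(), params=None, error: str | None = None):
        self.data["stages"][stage] = {
            "status": status,
            "outputs": sorted(str(o) for o in outputs),
            "params": params or {},
            **({"error": error} if error else {}),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(f"required input missing: {path}")
    return path


def _load_cohort(rundir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(rundir / "cohort.csv"))


def _load_tau_4d(rundir: Path, name: str) -> VolumeSet:
    import nibabel as nib

    img = nib.load(str(_require(rundir / name)))
    data = np.asarray(img.get_fdata(), float)  # (x, y, z, n)
    data = np.moveaxis(data, -1, 0)
    from .imaging_io import default_mask

    return VolumeSet(data=data, affine=np.asarray(img.affine), mask=default_mask(data))


def stage_simulate(config: RunConfig, rundir: Path) -> list:
    """Generate cohort, regional panel, painted tau volumes and atlas."""
    import nibabel as nib

    outputs = []
    cohort = generate_cohort(CohortSpec(seed=config.seed, **config.cohort))
    cohort.to_csv(rundir / "cohort.csv", index=False)
    outputs.append(rundir / "cohort.csv")

    n_img = min(config.imaging_n_subjects, len(cohort))
    sub = cohort.iloc[:n_img].reset_index(drop=True)
    sub.to_csv(rundir / "cohort_imaging.csv", index=False)
    outputs.append(rundir / "cohort_imaging.csv")

    truth = SpreadTruth(seed=config.seed, **config.spread)
    panel = generate_regional_tau(sub, truth)
    panel.to_csv(rundir / "panel.csv")
    outputs.append(rundir / "panel.csv")

    atlas = make_synthetic_atlas(
        shape=tuple(config.atlas["shape"]),
        voxel_size=config.atlas["voxel_size"],
        region_names=truth.regions,
        seed=config.seed,
    )
    nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine).to_filename(
        str(rundir / "atlas.nii.gz")
    )
    pd.DataFrame(
        {
            "label": sorted(atlas.names),
            "region": [atlas.names[k] for k in sorted(atlas.names)],
            "hemisphere": [atlas.hemisphere.get(k, "") for k in sorted(atlas.names)],
        }
    ).to_csv(rundir / "regions.csv", index=False)
    outputs += [rundir / "atlas.nii.gz", rundir / "regions.csv"]

    # tau accumulation couples to the composite score so the voxel-wise stage
    # has signal to find: regional baseline shifted by the UPSIT deviation
    upsit_dev = (sub["upsit"] - sub["upsit"].mean()).to_numpy()
    coupled = panel.baseline.copy()
    coupled.iloc[:, :] = coupled.to_numpy() - 0.01 * upsit_dev[:, None]
    for name, values in (("tau_baseline", coupled), ("tau_followup", panel.followup)):
        vol = paint_volumes(
            values, atlas, seed=config.seed, **config.paint
        )
        arr = np.moveaxis(vol.data, 0, -1).astype(np.float32)
        nib.Nifti1Image(arr, vol.affine).to_filename(str(rundir / f"{name}.nii.gz"))
        outputs.append(rundir / f"{name}.nii.gz")
    return outputs


def stage_norms(config: RunConfig, rundir: Path) -> list:
    cohort = _load_cohort(rundir)
    fit = aging_norms.fit_ransac_quadratic(
        cohort["age"], cohort["upsit"], seed=config.seed, **config.ransac
    )
    dev = aging_norms.deviation_scores(fit, cohort["age"], cohort["upsit"])
    pd.DataFrame(
        {"subject_id": cohort["subject_id"], "deviation": dev, "inlier": fit.inlier_mask}
    ).to_csv(rundir / "norms_deviations.csv", index=False)
    rates = aging_norms.odorant_rates(cohort)
    rates.to_csv(rundir / "odorant_rates.csv")
    (rundir / "norms_fit.json").write_text(
        json.dumps(
            {
                "coeffs": list(fit.coeffs),
                "n_inliers": fit.n_inliers,
                "threshold": fit.threshold,
                "n_iter": fit.n_iter,
                "sample_size": fit.sample_size,
            },
            indent=2,
        )
    )
    return [rundir / "norms_deviations.csv", rundir / "odorant_rates.csv", rundir / "norms_fit.json"]


def stage_voxelwise(config: RunConfig, rundir: Path) -> list:
    table = pd.read_csv(_require(rundir / "cohort_imaging.csv"))
    vol = _load_tau_4d(rundir, "tau_baseline.nii.gz")
    design = build_design(table, predictor="upsit", covariates=config.covariates)
    smap = voxel_assoc.fit_voxel_glm(vol, design)
    fwhm = voxel_assoc.estimate_smoothness(voxel_assoc.glm_residuals(vol, design))
    rng = substream(config.seed, "voxelwise")
    res = voxel_assoc.cluster_correct(
        smap,
        fwhm_est=fwhm,
        voxel_p=config.cluster["voxel_p"],
        n_iter=config.cluster["n_iter"],
        seed=int(rng.integers(2**31)),
    )
    write_map(vol.unmask(smap.z, fill=0.0), vol.affine, rundir / "upsit_zmap.nii.gz")
    null = voxel_assoc.odorant_count_null(
        vol.mask,
        vol.voxel_sizes,
        fwhm,
        n_iter=config.count_null["n_iter"],
        n_maps=config.count_null["n_maps"],
        alpha=config.alpha,
        seed=int(rng.integers(2**31)),
    )
    maps = []
    for col in ODORANT_COLUMNS:
        resp = table[col].to_numpy()
        if resp.min() == resp.max():
            maps.append(None)
            continue
        d = build_design(table, predictor=col, covariates=config.covariates)
        maps.append(voxel_assoc.fit_voxel_glm(vol, d))
    cmap = voxel_assoc.count_map(maps, null.threshold_count, alpha=config.alpha)
    write_map(cmap.counts_volume(vol.mask), vol.affine, rundir / "odorant_count_map.nii.gz")
    summary = {
        "fwhm_est_mm": fwhm,
        "n_clusters": int(res.n_clusters),
        "significant_clusters": res.significant(config.alpha).tolist(),
        "cluster_sizes": res.sizes.tolist(),
        "cluster_p": res.cluster_p.tolist(),
        "threshold_count": null.threshold_count,
        "n_flagged_voxels": int(cmap.flagged.sum()),
        "missing_odorants": cmap.missing,
    }
    (rundir / "voxelwise_summary.json").write_text(json.dumps(summary, indent=2))
    return [
        rundir / "upsit_zmap.nii.gz",
        rundir / "odorant_count_map.nii.gz",
        rundir / "voxelwise_summary.json",
    ]


def stage_biomarker(config: RunConfig, rundir: Path) -> list:
    table = pd.read_csv(_require(rundir / "cohort_imaging.csv"))
    vol = _load_tau_4d(rundir, "tau_baseline.nii.gz")
    M = odorant_biomarker.build_assoc_matrix(table, {"tau": vol}, covariates=config.covariates)
    comps = odorant_biomarker.pca_components(M, n_components=config.n_components)
    odorant_biomarker.loadings_table(comps).to_csv(rundir / "biomarker_loadings.csv")
    score = odorant_biomarker.score_subjects(comps[0], table)
    pd.DataFrame({"subject_id": table["subject_id"], "score": score.scores}).to_csv(
        rundir / "biomarker_scores.csv", index=False
    )
    fwhm = voxel_assoc.estimate_smoothness(
        voxel_assoc.glm_residuals(
            vol, build_design(table, predictor="upsit", covariates=config.covariates)
        )
    )
    rng = substream(config.seed, "biomarker_stage")
    smap, res = odorant_biomarker.backproject(
        score,
        vol,
        table,
        covariates=config.covariates,
        fwhm_est=fwhm,
        voxel_p=config.cluster["voxel_p"],
        n_iter=config.cluster["n_iter"],
        seed=int(rng.integers(2**31)),
    )
    write_map(vol.unmask(smap.z, fill=0.0), vol.affine, rundir / "biomarker_zmap.nii.gz")
    (rundir / "biomarker_summary.json").write_text(
        json.dumps(
            {
                "variance_explained": [c.variance_explained for c in comps],
                "significant_clusters": res.significant(config.alpha).tolist(),
            },
            indent=2,
        )
    )
    return [
        rundir / "biomarker_loadings.csv",
        rundir / "biomarker_scores.csv",
        rundir / "biomarker_zmap.nii.gz",
        rundir / "biomarker_summary.json",
    ]


def stage_tracts(config: RunConfig, rundir: Path) -> list:
    table = pd.read_csv(_require(rundir / "cohort_imaging.csv"))
    spec = TractPhantomSpec(seed=config.seed, **config.tract)
    if not spec.effect_segments:
        spec.effect_segments = tuple(range(40, 61))
    mask, md = generate_tract_md(table, spec)
    skel = tract_stats.skeletonize(
        mask.mask, mask.affine, mask.source_point, mask.target_point, n_segments=spec.n_segments
    )
    prof = tract_stats.segment_profiles(skel, md)
    res = tract_stats.along_tract_glm(
        prof, table, predictor="upsit", covariates=[c for c in config.covariates if c != "apoe4"]
    )
    res.to_frame().to_csv(rundir / "tract_segments.csv", index=False)
    write_map(skel.assignment_volume().astype(float), mask.affine, rundir / "tract_segments.nii.gz")
    return [rundir / "tract_segments.csv", rundir / "tract_segments.nii.gz"]


def _read_panel(rundir: Path) -> RegionalTauPanel:
    frame = pd.read_csv(_require(rundir / "panel.csv"))
    base = frame[[c for c in frame.columns if c.startswith("baseline_")]].copy()
    base.columns = [c.removeprefix("baseline_") for c in base.columns]
    fol = frame[[c for c in frame.columns if c.startswith("followup_")]].copy()
    fol.columns = [c.removeprefix("followup_") for c in fol.columns]
    return RegionalTauPanel(baseline=base, followup=fol, interval=frame["interval"])


def stage_graph(config: RunConfig, rundir: Path) -> list:
    table = pd.read_csv(_require(rundir / "cohort_imaging.csv"))
    panel = _read_panel(rundir)
    g = spread_graph.tau_connectivity(
        panel, covariates=table[config.graph_covariates], alpha=config.alpha
    )
    g.r.to_csv(rundir / "graph_r.csv")
    g.p.to_csv(rundir / "graph_p.csv")
    g.adjacency().to_csv(rundir / "graph_adjacency.csv")
    spread_graph.node_degrees(g).to_csv(rundir / "graph_degrees.csv")
    skel = spread_graph.pc_skeleton(panel.baseline, **config.pc)
    oriented = spread_graph.orient_backbone(skel, g)
    oriented.edge_list().to_csv(rundir / "backbone_edges.csv", index=False)
    seps = {" - ".join(sorted(k)): list(v) for k, v in skel.separating_sets.items()}
    (rundir / "backbone_sepsets.json").write_text(json.dumps(seps, indent=2, sort_keys=True))
    return [
        rundir / "graph_r.csv",
        rundir / "graph_p.csv",
        rundir / "graph_adjacency.csv",
        rundir / "graph_degrees.csv",
        rundir / "backbone_edges.csv",
        rundir / "backbone_sepsets.json",
    ]


def stage_genes(config: RunConfig, rundir: Path) -> list:
    truth = ExpressionTruth(seed=config.seed, **config.expression)
    expr = generate_expression(truth)
    expr.to_csv(rundir / "expression.csv", meta_path=rundir / "expression_regions.csv")
    cx = gene_coexpr.coexpression(expr)
    lo, hi = config.gene_k_range
    clusters = gene_coexpr.cluster_genes(cx, k_range=range(lo, hi + 1))
    clusters.labels.to_csv(rundir / "gene_clusters.csv")
    gene_coexpr.cluster_maps(expr, clusters).to_csv(rundir / "gene_cluster_maps.csv")
    # synthetic trait catalog extract keyed by the run seed
    rng = substream(config.seed, "gene_traits")
    genes = list(expr.values.index)
    traits = {
        "tau burden": "tau",
        "amyloid load": "amyloid",
        "alzheimer risk": "alzheimer",
        "longevity": "aging",
        "memory score": "cognition",
        "cortical thickness": "brain",
    }
    rows = []
    for g in rng.choice(genes, size=min(30, len(genes)), replace=False):
        t = rng.choice(list(traits))
        rows.append({"gene": g, "trait": t, "p": float(10 ** rng.uniform(-12, -5.01))})
    net = gene_coexpr.gene_trait_network(pd.DataFrame(rows), traits)
    net.gene_domain.to_csv(rundir / "gene_domain_network.csv", index=False)
    (rundir / "genes_summary.json").write_text(
        json.dumps({"selected_k": clusters.k, "silhouette_by_k": clusters.silhouette_by_k}, indent=2)
    )
    return [
        rundir / "expression.csv",
        rundir / "gene_clusters.csv",
        rundir / "gene_cluster_maps.csv",
        rundir / "gene_domain_network.csv",
        rundir / "genes_summary.json",
    ]


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "norms": stage_norms,
    "voxelwise": stage_voxelwise,
    "biomarker": stage_biomarker,
    "tracts": stage_tracts,
    "graph": stage_graph,
    "genes": stage_genes,
}


def run_stage(stage: str, config: RunConfig, rundir, manifest: Manifest | None = None):
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or Manifest(rundir, config)
    try:
        outputs = STAGE_FUNCS[stage](config, rundir)
    except Exception as exc:
        manifest.record(stage, "failed", error=f"{type(exc).__name__}: {exc}")
        raise
    manifest.record(stage, "ok", outputs=[Path(o).name for o in outputs])
    return outputs


def run_all(config: RunConfig, rundir) -> Path:
    """Execute every stage in dependency order; return the run directory."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(rundir / "config.yaml")
    manifest = Manifest(rundir, config)
    for stage in STAGES:
        logger.info("running stage %s", stage)
        run_stage(stage, config, rundir, manifest)
    return rundir
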