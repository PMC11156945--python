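"""Synthetic cohorts, tau panels, volumes, tract phantoms and expression data.

Every downstream stage of the pipeline is validated against data produced
here, with planted ground truth: a quadratic normative aging curve with gross
outliers, regional tau with a known directed spreading structure between two
visits, tube-shaped tract phantoms with microstructure effects on known
segments, and genes x regions expression with planted co-expression clusters.

All generators are pure functions of (spec, seed): repeated calls with the
same spec are bitwise identical. A single global seed can be fanned out to
per-component substreams with :func:`substream`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import AtlasError, GeometryError, ParameterError, SchemaError
from .imaging_io import ODORANT_COLUMNS, RegionAtlas, VolumeSet

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default region set for the spreading analyses: primary olfactory regions
#: plus the medial temporal lobe structures feeding them.
DEFAULT_REGIONS = ("AON", "TUR", "PirF", "PirT", "Ent", "Amyg", "Hipp", "Parahipp")

#: Planted directed spreading: medial temporal structures seed the olfactory
#: system (amygdala -> piriform, entorhinal -> AON, parahippocampus -> tubercle).
DEFAULT_EDGES = (("Amyg", "PirF", 0.05), ("Ent", "AON", 0.05), ("Parahipp", "TUR", 0.05))


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible RNG substream keyed by a string label."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _default_difficulties() -> np.ndarray:
    # Spread so identification rates range from >90% (easy items such as
    # onion/peanut/smoke in the real instrument) down to <60% (lime/lemon).
    return np.linspace(0.05, 0.55, 40)


@dataclass
class CohortSpec:
    """Parameters of the synthetic aging cohort.

    ``quadratic_coeffs`` (a0, a1, a2) define the mean composite score
    a0 + a1*age + a2*age^2 (default peaks near age 55 at 36/40 and decays
    in the eighth decade). ``score_noise_sd`` is the dispersion of the
    composite around the age trend, in UPSIT points; ``outlier_fraction`` of
    subjects are shifted by ``outlier_shift`` points (a gross deficit well
    beyond the 6-point inlier band used by the normative fit).
    """

    n_subjects: int = 418
    age_range: tuple = (55.0, 90.0)
    quadratic_coeffs: tuple = (5.75, 1.1, -0.01)
    odorant_difficulties: np.ndarray = field(default_factory=_default_difficulties)
    outlier_fraction: float = 0.0
    outlier_shift: float = -15.0
    score_noise_sd: float = 2.0
    covariate_effect_sizes: dict = field(default_factory=dict)
    difficulty_scale: float = 1.0
    response_model: str = "competition"
    interval_mean: float = 2.38
    interval_sd: float = 0.45
    seed: int = 0

    def validate(self):
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if not (0 <= self.outlier_fraction < 1):
            raise ParameterError("outlier_fraction must be in [0, 1)")
        d = np.asarray(self.odorant_difficulties, dtype=float)
        if d.shape != (40,):
            raise ParameterError("exactly 40 odorant difficulties required")
        if ((d <= 0) | (d >= 1)).any():
            raise ParameterError("odorant difficulties must lie in (0, 1)")
        if self.score_noise_sd < 0 or self.interval_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if self.response_model not in ("competition", "independent"):
            raise ParameterError("response_model must be 'competition' or 'independent'")
        return self


def _calibrated_probabilities(targets: np.ndarray, difficulties: np.ndarray, scale: float) -> np.ndarray:
    """Per-subject odorant probabilities sigma(a_i + b_k) with sum_k p = target.

    b_k = logit(1 - difficulty_k)/scale; a_i solved by monotone bisection.
    """
    b = np.log((1 - difficulties) / difficulties) / max(scale, 1e-12)
    lo = np.full(len(targets), -30.0)
    hi = np.full(len(targets), 30.0)
    for _ in range(60):
        mid = (lo + hi) / 2.0
        s = 1.0 / (1.0 + np.exp(-(mid[:, None] + b[None, :])))
        total = s.sum(axis=1)
        lo = np.where(total < targets, mid, lo)
        hi = np.where(total < targets, hi, mid)
    a = (lo + hi) / 2.0
    return 1.0 / (1.0 + np.exp(-(a[:, None] + b[None, :])))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a subject table with planted normative structure.

    The composite score of subject i targets the quadratic age trend plus
    Gaussian noise (plus the outlier shift and any covariate effects), rounded
    and clipped to [0, 40]. Under the default ``response_model="competition"``
    the identified odorants are the target-count items with the highest
    utilities logit(1 - difficulty)/scale + Gumbel noise, so easier odorants
    are identified more often while the composite equals its target exactly
    (at score_noise_sd = 0 the composite is exactly the rounded trend).
    ``response_model="independent"`` instead draws each response as an
    independent Bernoulli whose per-odorant probabilities are calibrated so
    their sum matches the target (conditional independence given age, at the
    cost of extra binomial composite noise). ``is_outlier`` records the
    planted outliers.
    """
    spec.validate()
    rng = substream(spec.seed, "cohort")
    n = spec.n_subjects
    ages = rng.uniform(*spec.age_range, size=n)
    a0, a1, a2 = spec.quadratic_coeffs
    trend = a0 + a1 * ages + a2 * ages**2

    sex = rng.integers(0, 2, size=n)
    apoe4 = (rng.random(n) < 0.3).astype(int)
    smoking = (rng.random(n) < 0.3).astype(int)
    education = np.clip(np.round(rng.normal(16, 2.5, size=n)), 8, 20)
    interval = np.clip(rng.normal(spec.interval_mean, spec.interval_sd, size=n), 0.25, None)

    target = trend + rng.normal(0.0, spec.score_noise_sd, size=n)
    for cov, slope in spec.covariate_effect_sizes.items():
        target = target + slope * {"sex": sex, "apoe4": apoe4, "smoking": smoking,
                                   "education": education, "age": ages}[cov]
    n_out = int(round(spec.outlier_fraction * n))
    outliers = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    target[outliers] += spec.outlier_shift
    scores = np.clip(np.rint(target), 0, 40).astype(int)

    d = np.asarray(spec.odorant_difficulties, dtype=float)
    if spec.response_model == "competition":
        base_util = np.log((1 - d) / d) / max(spec.difficulty_scale, 1e-12)
        util = base_util[None, :] + rng.gumbel(size=(n, 40))
        order = np.argsort(-util, axis=1, kind="stable")
        responses = np.zeros((n, 40), dtype=int)
        rows = np.repeat(np.arange(n), scores)
        cols = np.concatenate([order[i, : scores[i]] for i in range(n)]) if n else np.array([], int)
        responses[rows, cols] = 1
        scores = responses.sum(axis=1)
    else:
        probs = _calibrated_probabilities(np.clip(target, 0.5, 39.5), d, spec.difficulty_scale)
        responses = (rng.random((n, 40)) < probs).astype(int)
        scores = responses.sum(axis=1)

    centered = scores - scores.mean() if n > 1 else scores * 0.0
    pacc_base = 0.05 * centered + rng.normal(0, 1.0, size=n)
    pacc_follow = pacc_base + 0.03 * centered * interval + rng.normal(0, 0.5, size=n)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": ages,
            "sex": sex,
            "apoe4": apoe4,
            "smoking": smoking,
            "education": education,
            "interval": interval,
        }
    )
    table[ODORANT_COLUMNS] = responses
    table["upsit"] = responses.sum(axis=1)
    table["pacc_baseline"] = pacc_base
    table["pacc_followup"] = pacc_follow
    table["is_outlier"] = False
    table.loc[outliers, "is_outlier"] = True
    return table


# ---------------------------------------------------------------------------
# Regional tau with planted spreading
# ---------------------------------------------------------------------------

@dataclass
class SpreadTruth:
    """Ground truth for the directional tau-spreading generator.

    ``edges`` are directed (source, target, beta) triples: follow-up tau at
    the target gains beta * baseline_source * interval SUVr. Defaults plant
    medial-temporal-to-olfactory spreading at realistic SUVr scales (baseline
    ~1.2 +/- 0.15 SUVr, longitudinal noise 0.02 SUVr over ~2.4 years).
    """

    regions: tuple = DEFAULT_REGIONS
    edges: tuple = DEFAULT_EDGES
    baseline_mean: float = 1.2
    baseline_sd: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self):
        names = set(self.regions)
        for src, dst, beta in self.edges:
            if src == dst:
                raise ParameterError(f"self-edge {src}->{dst} not allowed")
            if src not in names or dst not in names:
                raise SchemaError(f"edge {src}->{dst} references unknown region")
            if not np.isfinite(beta):
                raise ParameterError("transfer coefficients must be finite")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        return self

    def beta_matrix(self) -> np.ndarray:
        idx = {r: i for i, r in enumerate(self.regions)}
        B = np.zeros((len(self.regions), len(self.regions)))
        for src, dst, beta in self.edges:
            B[idx[src], idx[dst]] = beta
        return B


@dataclass
class RegionalTauPanel:
    """Subjects x regions tau at two visits plus the inter-scan interval."""

    baseline: pd.DataFrame
    followup: pd.DataFrame
    interval: pd.Series
    extra_nodes: pd.DataFrame | None = None  # baseline-side only (e.g. DRN MD)

    @property
    def regions(self) -> list:
        return list(self.baseline.columns)

    def to_csv(self, path) -> None:
        base = self.baseline.add_prefix("baseline_")
        fol = self.followup.add_prefix("followup_")
        out = pd.concat([base, fol], axis=1)
        out["interval"] = self.interval.to_numpy()
        if self.extra_nodes is not None:
            out = pd.concat([out, self.extra_nodes.add_prefix("extra_")], axis=1)
        out.to_csv(path, index=False)


def generate_regional_tau(cohort: pd.DataFrame, truth: SpreadTruth) -> RegionalTauPanel:
    """Two-visit regional tau with the planted directed transfer structure.

    baseline_r ~ N(baseline_mean, baseline_sd) i.i.d. per region;
    followup_j = baseline_j + sum_i beta_ij * baseline_i * interval + noise.
    """
    truth.validate()
    rng = substream(truth.seed, "regional_tau")
    n = len(cohort)
    k = len(truth.regions)
    if "interval" not in cohort.columns:
        raise SchemaError("cohort table lacks an 'interval' column")
    dt = cohort["interval"].to_numpy(dtype=float)
    base = rng.normal(truth.baseline_mean, truth.baseline_sd, size=(n, k))
    B = truth.beta_matrix()
    follow = base + (base @ B) * dt[:, None] + rng.normal(0, truth.noise_sd, size=(n, k))
    return RegionalTauPanel(
        baseline=pd.DataFrame(base, columns=list(truth.regions)),
        followup=pd.DataFrame(follow, columns=list(truth.regions)),
        interval=pd.Series(dt, name="interval"),
    )


# ---------------------------------------------------------------------------
# Atlas + painted volumes
# ---------------------------------------------------------------------------

def make_synthetic_atlas(
    shape=(24, 24, 24),
    voxel_size: float = 2.0,
    region_names=DEFAULT_REGIONS,
    region_radius: float = 2.2,
    seed: int = 0,
) -> RegionAtlas:
    """Small MNI-like grid with one spherical region per name.

    Region centers are placed on a jittered lattice so spheres never overlap;
    hemisphere tags alternate L/R by x position.
    """
    rng = substream(seed, "atlas")
    labels = np.zeros(shape, dtype=int)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * (np.array(shape) - 1) / 2.0
    k = len(region_names)
    side = int(np.ceil(k ** (1 / 3)))
    centers = []
    spacing = (np.array(shape) - 4) / max(side, 1)
    for i in range(k):
        ix, iy, iz = np.unravel_index(i, (side,) * 3)
        c = 2 + spacing * (np.array([ix, iy, iz]) + 0.5) + rng.uniform(-0.5, 0.5, 3)
        centers.append(c)
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    names, hemis = {}, {}
    for lab, (name, c) in enumerate(zip(region_names, centers), start=1):
        d2 = ((grid - c) ** 2).sum(axis=-1)
        labels[d2 <= region_radius**2] = lab
        names[lab] = name
        hemis[lab] = "L" if c[0] < shape[0] / 2 else "R"
    return RegionAtlas(labels=labels, affine=affine, names=names, hemisphere=hemis)


def paint_volumes(
    panel_values: pd.DataFrame,
    atlas: RegionAtlas,
    smoothing_fwhm: float = 0.0,
    voxel_noise_sd: float = 0.0,
    background: float = 0.0,
    seed: int = 0,
) -> VolumeSet:
    """Per-subject volumes with each region filled by its regional value.

    ``panel_values`` is subjects x regions (e.g. ``panel.baseline``). Voxel
    noise is added before Gaussian smoothing; ROI-mean extraction of the
    result recovers the regional values up to smoothing bias.
    """
    missing = [r for r in panel_values.columns if r not in atlas.names.values()]
    if missing:
        raise AtlasError(f"atlas lacks labels for regions: {missing}")
    for name in panel_values.columns:
        if not (atlas.labels == atlas.label_of(name)).any():
            raise AtlasError(f"region {name!r} has no voxels in the atlas")
    rng = substream(seed, "paint")
    n = len(panel_values)
    data = np.full((n,) + atlas.labels.shape, float(background))
    for name in panel_values.columns:
        sel = atlas.labels == atlas.label_of(name)
        data[:, sel] = panel_values[name].to_numpy()[:, None]
    if voxel_noise_sd > 0:
        data += rng.normal(0, voxel_noise_sd, size=data.shape)
    if smoothing_fwhm > 0:
        voxel = np.sqrt((np.diag(atlas.affine)[:3] ** 2))
        sigma = smoothing_fwhm * FWHM_TO_SIGMA / voxel
        data = gaussian_filter(data, sigma=(0, *sigma))
    mask = np.ones(atlas.labels.shape, bool)
    return VolumeSet(data=data, affine=atlas.affine, mask=mask)


# ---------------------------------------------------------------------------
# Tract phantom
# ---------------------------------------------------------------------------

def _default_control_points() -> np.ndarray:
    # A gently curved course through a 2 mm grid, ~60 mm long.
    return np.array(
        [[-28.0, -10.0, -6.0], [-10.0, 2.0, 0.0], [8.0, -4.0, 4.0], [28.0, 8.0, 8.0]]
    )


@dataclass
class TractPhantomSpec:
    """Tube phantom for the along-tract analysis.

    ``effect_segments`` (1-based indices) carry an MD change of
    ``effect_size`` (mm^2/s) per composite-score point of deviation from the
    sample mean. Default MD scale mirrors white matter (~0.8e-3 mm^2/s) with
    5e-5 voxel noise; the default 6 mm radius emulates the fat probabilistic
    tract masks of real data and keeps every one of the 100 segments
    populated on a 2 mm grid.
    """

    n_segments: int = 100
    curve_control_points: np.ndarray = field(default_factory=_default_control_points)
    radius: float = 6.0
    effect_segments: tuple = ()
    effect_size: float = 2.5e-6
    baseline_md: float = 0.8e-3
    md_noise_sd: float = 5e-5
    grid_shape: tuple = (40, 28, 24)
    voxel_size: float = 2.0
    seed: int = 0

    def validate(self):
        self.grid_shape = tuple(self.grid_shape)
        self.effect_segments = tuple(self.effect_segments)
        if self.n_segments < 2:
            raise ParameterError("n_segments must be >= 2")
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")
        pts = np.asarray(self.curve_control_points, float)
        if len(pts) < 2 or (np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-9).any():
            raise GeometryError("degenerate curve: repeated control points")
        return self


@dataclass
class TractMask:
    """Tube voxel mask plus the ground-truth segment of every mask voxel."""

    mask: np.ndarray
    affine: np.ndarray
    truth_segment: np.ndarray  # same shape as mask; 0 outside, 1..n inside
    curve_points: np.ndarray  # finely sampled centerline, world mm

    @property
    def source_point(self) -> np.ndarray:
        return self.curve_points[0]

    @property
    def target_point(self) -> np.ndarray:
        return self.curve_points[-1]


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline at n points equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, points[:, d])
    return out


def generate_tract_md(cohort: pd.DataFrame, spec: TractPhantomSpec):
    """Tube mask around the control-point curve plus per-subject MD volumes.

    Returns ``(TractMask, VolumeSet)``. MD at in-mask voxels is baseline +
    effect_size * (upsit - mean upsit) on effect segments + Gaussian noise.
    """
    spec.validate()
    rng = substream(spec.seed, "tract_md")
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -spec.voxel_size * (np.array(spec.grid_shape) - 1) / 2.0
    fine = _resample_polyline(np.asarray(spec.curve_control_points, float), 2000)
    # voxel centers in world coordinates
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij"), -1)
    world = idx * spec.voxel_size + affine[:3, 3]
    flat = world.reshape(-1, 3)
    from scipy.spatial import cKDTree

    tree = cKDTree(fine)
    dist, nearest = tree.query(flat)
    inside = dist <= spec.radius
    mask = inside.reshape(spec.grid_shape)
    if not mask.any():
        raise GeometryError("tube mask is empty on this grid")
    seg_len = (len(fine) - 1) / spec.n_segments
    seg_of_fine = np.minimum((np.arange(len(fine)) / seg_len).astype(int), spec.n_segments - 1) + 1
    truth = np.zeros(spec.grid_shape, dtype=int)
    truth.reshape(-1)[inside] = seg_of_fine[nearest[inside]]

    n = len(cohort)
    upsit_dev = cohort["upsit"].to_numpy(float) - cohort["upsit"].to_numpy(float).mean()
    data = np.full((n,) + spec.grid_shape, spec.baseline_md)
    effect_vox = np.isin(truth, list(spec.effect_segments)) & mask
    if spec.effect_size != 0 and effect_vox.any():
        data[:, effect_vox] += spec.effect_size * upsit_dev[:, None]
    data[:, mask] += rng.normal(0, spec.md_noise_sd, size=(n, int(mask.sum())))
    vol = VolumeSet(data=data, affine=affine, mask=mask)
    return TractMask(mask=mask, affine=affine, truth_segment=truth, curve_points=fine), vol


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    """Planted gene co-expression clusters over a 68-region cortical grid."""

    n_genes: int = 390
    n_regions: int = 68
    k_clusters: int = 4
    within_cluster_corr: float = 0.8
    hemisphere_shift: dict = field(default_factory=dict)  # cluster -> R-minus-L shift
    seed: int = 0

    def validate(self):
        if not (0 < self.within_cluster_corr < 1):
            raise ParameterError("within_cluster_corr must lie in (0, 1)")
        if self.k_clusters > self.n_genes or self.k_clusters < 1:
            raise ParameterError("k_clusters must lie in [1, n_genes]")
        if self.n_regions % 2:
            raise ParameterError("n_regions must be even (hemisphere split)")
        return self


@dataclass
class ExpressionMatrix:
    """Genes x regions expression with region metadata and optional truth."""

    values: pd.DataFrame
    region_meta: pd.DataFrame  # columns: region, hemisphere
    truth_labels: np.ndarray | None = None

    def to_csv(self, path, meta_path=None) -> None:
        self.values.to_csv(path)
        if meta_path is not None:
            self.region_meta.to_csv(meta_path, index=False)


def generate_expression(truth: ExpressionTruth) -> ExpressionMatrix:
    """Genes x regions matrix with k planted co-expression clusters.

    Gene g in cluster c is sqrt(w) * f_c + sqrt(1-w) * noise over regions,
    giving within-cluster pairwise correlation w and ~0 between clusters.
    """
    truth.validate()
    rng = substream(truth.seed, "expression")
    half = truth.n_regions // 2
    regions = [f"lh_region_{i:02d}" for i in range(1, half + 1)] + [
        f"rh_region_{i:02d}" for i in range(1, half + 1)
    ]
    hemis = ["L"] * half + ["R"] * half
    labels = np.repeat(np.arange(truth.k_clusters), int(np.ceil(truth.n_genes / truth.k_clusters)))[
        : truth.n_genes
    ]
    factors = rng.normal(size=(truth.k_clusters, truth.n_regions))
    w = truth.within_cluster_corr
    noise = rng.normal(size=(truth.n_genes, truth.n_regions))
    values = np.sqrt(w) * factors[labels] + np.sqrt(1 - w) * noise
    for c, shift in truth.hemisphere_shift.items():
        values[labels == c, half:] += shift
    genes = [f"gene_{i:04d}" for i in range(1, truth.n_genes + 1)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=regions),
        region_meta=pd.DataFrame({"region": regions, "hemisphere": hemis}),
        truth_labels=labels,
    )
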