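"""Voxel-wise GLMs and Monte-Carlo multiple-comparison corrections.

Three correction machines live here:

* :func:`estimate_smoothness` — Gaussian-equivalent FWHM of a residual field
  from the variance of spatial first differences (a field of white noise has
  an equivalent FWHM of about one voxel under this convention, and smoothing
  adds in quadrature).
* :func:`odorant_count_null` — the per-voxel "how many of 40 independent maps
  are significant at alpha by chance" null, built from smoothness-matched
  Gaussian maps; yields the minimal odorant count deemed non-chance
  (family-wise over the mask via the max-count distribution).
* :func:`cluster_correct` — cluster-wise correction of a single statistic
  map against the max-cluster-size distribution of smoothness-matched null
  maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, stats

from ._stats import Z_CAP, ols_t, t_to_z
from .exceptions import EstimationError, ParameterError
from .imaging_io import DesignMatrix, VolumeSet

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StatMap:
    """Voxel-wise T and Z statistics for one predictor of interest.

    ``t``/``z`` are (V,) vectors over the in-mask voxels of ``mask``; ``z``
    is the sign-preserving normal-quantile transform of the two-sided t
    p-value, capped (and flagged in ``capped``) where p underflows.
    """

    t: np.ndarray
    z: np.ndarray
    df: int
    predictor: str
    mask: np.ndarray
    affine: np.ndarray
    capped: np.ndarray

    def z_volume(self) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.z
        return out

    def p_values(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.t), self.df)


def fit_voxel_glm(vol: VolumeSet, design: DesignMatrix) -> StatMap:
    """Per-voxel OLS of the volume data on the design matrix."""
    X = design.values
    if len(X) != vol.n_subjects:
        raise ParameterError("design rows do not match number of subjects")
    Y = vol.masked()
    t, df, _, _ = ols_t(X, Y, design.predictor_index)
    z, capped = t_to_z(t, df)
    if capped.any():
        logger.info("%d voxels with underflowing p capped at |Z|=%.1f", capped.sum(), Z_CAP)
    return StatMap(
        t=t, z=z, df=df, predictor=design.predictor,
        mask=vol.mask, affine=vol.affine, capped=capped,
    )


def glm_residuals(vol: VolumeSet, design: DesignMatrix) -> VolumeSet:
    """Residual volumes of the voxel-wise GLM (for smoothness estimation)."""
    X = design.values
    _, _, _, resid = ols_t(X, vol.masked(), design.predictor_index)
    data = np.zeros_like(vol.data)
    data[:, vol.mask] = resid
    return VolumeSet(data=data, affine=vol.affine, mask=vol.mask)


def estimate_smoothness(residuals: VolumeSet, min_voxels: int = 100) -> float:
    """Gaussian-equivalent FWHM (mm) of the residual fields.

    For each axis the variance of first differences between neighboring
    in-mask voxels is compared with the field variance; under a Gaussian
    autocorrelation model with kernel sd s, var(diff)/var = d^2/(2 s^2) for
    spacing d, giving FWHM = 2.3548 * d * sqrt(var / (2 var_diff)). Estimates
    are averaged over axes and subjects. White noise yields ~1.18 voxels.
    """
    mask = residuals.mask
    if mask.sum() < min_voxels:
        raise EstimationError(f"mask too small for smoothness estimation ({mask.sum()} voxels)")
    voxel = residuals.voxel_sizes
    fwhms = []
    for s in range(residuals.n_subjects):
        v = residuals.data[s]
        var = v[mask].var()
        if var <= 0:
            raise EstimationError("constant residuals: zero variance")
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
            if pair.sum() < 10:
                continue
            diff = v[tuple(sl_b)][pair] - v[tuple(sl_a)][pair]
            var_diff = np.mean(diff**2)
            if var_diff <= 0:
                continue
            s_mm = voxel[ax] * np.sqrt(var / (2.0 * var_diff))
            fwhms.append(s_mm / FWHM_TO_SIGMA)
    if not fwhms:
        raise EstimationError("no valid neighbor pairs for smoothness estimation")
    return float(np.mean(fwhms))


def _kernel_lag1_corr(sigma: float) -> float:
    """Lag-1 autocorrelation of white noise filtered with a discrete Gaussian."""
    if sigma <= 1e-6:
        return 0.0
    half = max(int(np.ceil(6 * sigma)), 3)
    w = np.exp(-np.arange(-half, half + 1) ** 2 / (2.0 * sigma**2))
    return float((w[:-1] * w[1:]).sum() / (w * w).sum())


def _smoothing_sigma_vox(voxel_sizes, fwhm: float) -> tuple:
    """Kernel sd (voxels) such that the smoothness *estimator* applied to the
    resulting field returns exactly ``fwhm``.

    The estimator maps lag-1 autocorrelation rho to
    FWHM = 2.3548 d / (2 sqrt(1 - rho)); inverting gives the target rho per
    axis, and the kernel sd solving it is found by bisection on the discrete
    kernel's autocorrelation. Targets at or below the white-noise equivalent
    (~1.18 voxels) need no smoothing.
    """
    out = []
    for d in np.asarray(voxel_sizes, float):
        rho_target = 1.0 - (2.3548 * d / (2.0 * fwhm)) ** 2 if fwhm > 0 else 0.0
        if rho_target <= 0:
            out.append(0.0)
            continue
        lo, hi = 1e-3, 50.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _kernel_lag1_corr(mid) < rho_target:
                lo = mid
            else:
                hi = mid
        out.append(0.5 * (lo + hi))
    return tuple(out)


@lru_cache(maxsize=8)
def _smoothed_noise_sd(shape: tuple, sigma_vox: tuple) -> np.ndarray:
    """Exact per-voxel sd of Gaussian-filtered unit white noise.

    The filter is separable, so the per-voxel output variance is the outer
    product of the per-axis row norms of the 1D filter matrices (reflect
    boundaries included).
    """
    axis_norms = []
    for n, s in zip(shape, sigma_vox):
        if s <= 1e-6:
            axis_norms.append(np.ones(n))
            continue
        W = ndimage.gaussian_filter1d(np.eye(n), sigma=s, axis=1, mode="reflect")
        axis_norms.append(np.sqrt((W**2).sum(axis=1)))
    var = np.einsum("i,j,k->ijk", *(a**2 for a in axis_norms))
    return np.sqrt(var)


def _null_maps(rng, n_maps: int, shape, mask, voxel_sizes, fwhm: float) -> np.ndarray:
    """Unit-variance smoothness-matched Gaussian null maps, (n_maps, V).

    White noise is smoothed to the target FWHM and divided by the exact
    per-voxel sd of the smoothing operator, so every voxel is marginally
    N(0, 1) — like a GLM Z map — while map-level fluctuations are retained
    (per-map empirical standardization would suppress them and shrink the
    null's cluster sizes).
    """
    maps = rng.standard_normal((n_maps, *shape))
    sigma_vox = _smoothing_sigma_vox(voxel_sizes, fwhm)
    if max(sigma_vox) > 1e-6:
        maps = ndimage.gaussian_filter(maps, sigma=(0, *sigma_vox))
        maps /= _smoothed_noise_sd(tuple(shape), sigma_vox)[None]
    return maps[:, mask]


@dataclass
class CountNull:
    """Null distribution of per-voxel significant-map counts."""

    threshold_count: int
    max_count_distribution: np.ndarray  # P(max over mask >= c) for c = 0..n_maps
    count_histogram: np.ndarray  # pooled per-voxel count frequencies, length n_maps+1
    n_iter: int
    n_maps: int
    alpha: float
    fwe_alpha: float
    fwhm: float
    saturated: bool = False  # True when even c = n_maps is not rare enough


def odorant_count_null(
    mask: np.ndarray,
    voxel_sizes,
    fwhm_est: float,
    n_iter: int = 5000,
    n_maps: int = 40,
    alpha: float = 0.05,
    fwe_alpha: float = 0.05,
    seed: int | None = None,
) -> CountNull:
    """Monte-Carlo null for the odorant-count maps.

    Each iteration draws ``n_maps`` independent smoothness-matched Gaussian
    maps, thresholds each at two-sided ``alpha``, and records how many maps
    are significant at every voxel. ``threshold_count`` is the smallest count
    c whose family-wise probability P(any voxel reaches c) is below
    ``fwe_alpha``.
    """
    if n_iter < 100:
        raise ParameterError("n_iter < 100 gives an unstable null; refused")
    mask = np.asarray(mask, bool)
    voxel_sizes = np.asarray(voxel_sizes, float)
    if fwhm_est < voxel_sizes.min() - 1e-9:
        raise ParameterError("fwhm_est below voxel size is not representable")
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.isf(alpha / 2.0) if alpha > 0 else np.inf
    hist = np.zeros(n_maps + 1, dtype=np.int64)
    max_counts = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        flat = _null_maps(rng, n_maps, mask.shape, mask, voxel_sizes, fwhm_est)
        counts = (np.abs(flat) > zcrit).sum(axis=0)
        hist += np.bincount(counts, minlength=n_maps + 1)
        max_counts[it] = counts.max()
    exceed = np.array([(max_counts >= c).mean() for c in range(n_maps + 1)])
    passing = np.nonzero(exceed < fwe_alpha)[0]
    saturated = passing.size == 0
    threshold_count = int(passing[0]) if passing.size else n_maps + 1
    threshold_count = max(threshold_count, 1)
    return CountNull(
        threshold_count=threshold_count,
        max_count_distribution=exceed,
        count_histogram=hist,
        n_iter=n_iter,
        n_maps=n_maps,
        alpha=alpha,
        fwe_alpha=fwe_alpha,
        fwhm=fwhm_est,
        saturated=saturated,
    )


@dataclass
class CountMap:
    """Per-voxel count of odorant tests significant at alpha."""

    counts: np.ndarray  # (V,) integer counts over the mask
    flagged: np.ndarray  # counts >= threshold_count
    alpha: float
    threshold_count: int
    n_valid_maps: int
    missing: list = field(default_factory=list)

    def counts_volume(self, mask: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[mask] = self.counts
        return out


def count_map(stat_maps, threshold_count: int, alpha: float = 0.05) -> CountMap:
    """Count, per voxel, how many odorant maps are significant at alpha.

    ``stat_maps`` is a sequence of :class:`StatMap` (entries may be None for
    odorants whose map is undefined, e.g. identified by everyone; those are
    excluded from the count and recorded in ``missing``).
    """
    valid = [(k, m) for k, m in enumerate(stat_maps) if m is not None]
    if not valid:
        raise ParameterError("no valid stat maps")
    missing = [k for k, m in enumerate(stat_maps) if m is None]
    V = valid[0][1].z.shape[0]
    counts = np.zeros(V, dtype=int)
    for _, m in valid:
        p = m.p_values()
        counts += (p < alpha).astype(int)
    return CountMap(
        counts=counts,
        flagged=counts >= threshold_count,
        alpha=alpha,
        threshold_count=threshold_count,
        n_valid_maps=len(valid),
        missing=missing,
    )


@dataclass
class ClusterResult:
    """Suprathreshold clusters with Monte-Carlo family-wise p-values."""

    labels: np.ndarray  # 3D integer cluster labels (0 = background)
    sizes: np.ndarray  # voxel count per cluster, ordered by label
    cluster_p: np.ndarray  # MC p per cluster, (1 + #null >= size)/(n_iter + 1)
    below_resolution: np.ndarray  # True where no null max reached the size
    voxel_threshold: float
    n_iter: int
    fwhm_est: float
    null_max_sizes: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return np.nonzero(self.cluster_p < alpha)[0] + 1


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ParameterError("connectivity must be 6 or 26")


def cluster_correct(
    stat_map: StatMap,
    fwhm_est: float,
    voxel_p: float = 0.05,
    n_iter: int = 10000,
    seed: int | None = None,
    connectivity: int = 26,
    two_sided: bool = True,
    null_max_sizes: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-wise Monte-Carlo correction of a statistic map.

    Suprathreshold voxels (|Z| above the two-sided ``voxel_p`` quantile) are
    grouped by ``connectivity`` (26-neighborhood default); each observed
    cluster's size is referred to the distribution of the maximum cluster
    size across ``n_iter`` smoothness-matched Gaussian null maps thresholded
    identically. ``null_max_sizes`` may be supplied to reuse a previously
    computed null distribution for the same mask/threshold/smoothness.

    An empty suprathreshold set returns an empty result, not an error.
    """
    struct = _connectivity_structure(connectivity)
    zcrit = stats.norm.isf(voxel_p / 2.0) if two_sided else stats.norm.isf(voxel_p)
    mask = stat_map.mask
    voxel_sizes = np.sqrt((stat_map.affine[:3, :3] ** 2).sum(axis=0))

    if null_max_sizes is None:
        null_max_sizes = simulate_null_max_sizes(
            mask, voxel_sizes, fwhm_est, zcrit, n_iter, seed,
            connectivity=connectivity, two_sided=two_sided,
        )
    else:
        null_max_sizes = np.asarray(null_max_sizes)
        n_iter = len(null_max_sizes)

    zvol = stat_map.z_volume()
    supra = (np.abs(zvol) > zcrit) if two_sided else (zvol > zcrit)
    supra &= mask
    labels, n_clusters = ndimage.label(supra, structure=struct)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_clusters + 1))
    sizes = np.asarray(sizes, dtype=int)
    exceed = np.array([(null_max_sizes >= s).sum() for s in sizes], dtype=int)
    cluster_p = (1.0 + exceed) / (n_iter + 1.0)
    return ClusterResult(
        labels=labels,
        sizes=sizes,
        cluster_p=cluster_p,
        below_resolution=exceed == 0,
        voxel_threshold=voxel_p,
        n_iter=n_iter,
        fwhm_est=fwhm_est,
        null_max_sizes=null_max_sizes,
    )


def simulate_null_max_sizes(
    mask: np.ndarray,
    voxel_sizes,
    fwhm_est: float,
    zcrit: float,
    n_iter: int,
    seed: int | None,
    connectivity: int = 26,
    two_sided: bool = True,
) -> np.ndarray:
    """Max suprathreshold cluster size per smoothness-matched null map."""
    if n_iter < 100:
        raise ParameterError("n_iter < 100 gives an unstable null; refused")
    struct = _connectivity_structure(connectivity)
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, bool)
    out = np.zeros(n_iter, dtype=int)
    vol = np.zeros(mask.shape)
    for it in range(n_iter):
        flat = _null_maps(rng, 1, mask.shape, mask, voxel_sizes, fwhm_est)[0]
        vol[:] = 0.0
        vol[mask] = flat
        supra = (np.abs(vol) > zcrit) if two_sided else (vol > zcrit)
        supra &= mask
        labels, n = ndimage.label(supra, structure=struct)
        if n:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
            out[it] = int(np.max(sizes))
    return out
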