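"""Along-tract statistics: skeletonization, segment assignment, per-segment GLM.

A tract mask is shrunk to a centerline (masked shortest path between the two
endpoints, then symmetric smoothing), resampled at equal arc length and cut
into 100 contiguous same-size segments. Every tract voxel is assigned to the
closest segment; per-subject mean diffusivity per segment is the outcome of
a per-segment GLM against the odor-identification predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from ._stats import ols_t, t_to_z, two_sided_p_from_t
from .exceptions import GeometryError, ParameterError
from .imaging_io import DesignMatrix, VolumeSet, build_design

logger = logging.getLogger(__name__)


@dataclass
class TractSkeleton:
    """Equal-arc-length centerline with voxel-to-segment assignment."""

    centerline: np.ndarray  # (n_fine, 3) world mm, source -> target
    arc_length: np.ndarray  # cumulative, mm, strictly increasing
    segment_boundaries: np.ndarray  # (n_segments + 1,) arc-length cut points
    voxel_assignment: dict  # (i, j, k) -> segment index 1..n_segments
    n_segments: int
    mask: np.ndarray
    affine: np.ndarray

    def assignment_volume(self) -> np.ndarray:
        out = np.zeros(self.mask.shape, dtype=int)
        for ijk, seg in self.voxel_assignment.items():
            out[ijk] = seg
        return out

    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.segment_boundaries)


def _world_coords(idx: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _mask_graph(mask: np.ndarray, affine: np.ndarray):
    """Sparse 26-neighborhood graph over mask voxels, edge weight = mm step."""
    idx = np.argwhere(mask)
    lin = -np.ones(mask.shape, dtype=int)
    lin[tuple(idx.T)] = np.arange(len(idx))
    voxel = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    rows, cols, w = [], [], []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    for off in offsets:
        nb = idx + off
        ok = ((nb >= 0) & (nb < mask.shape)).all(axis=1)
        nb = nb[ok]
        src = np.arange(len(idx))[ok]
        tgt = lin[tuple(nb.T)]
        hit = tgt >= 0
        rows.append(src[hit])
        cols.append(tgt[hit])
        w.append(np.full(hit.sum(), np.linalg.norm(np.asarray(off) * voxel)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    n = len(idx)
    g = sparse.coo_matrix((w, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr(), idx, lin


def _smooth_polyline(points: np.ndarray, window: int = 9, iterations: int = 3) -> np.ndarray:
    """Symmetric moving-average smoothing (reversal-invariant)."""
    if len(points) < 3:
        return points
    out = points.astype(float)
    for _ in range(iterations):
        pad = np.concatenate([out[1 : window // 2 + 1][::-1], out, out[-window // 2 - 1 : -1][::-1]])
        kernel = np.ones(window) / window
        out = np.stack([np.convolve(pad[:, d], kernel, mode="valid") for d in range(3)], axis=1)
        out[0], out[-1] = points[0], points[-1]
    return out


def _resample_equal_arc(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise GeometryError("zero-length centerline")
    targets = np.linspace(0.0, arc[-1], n)
    return np.stack([np.interp(targets, arc, points[:, d]) for d in range(3)], axis=1)


def skeletonize(
    mask: np.ndarray,
    affine: np.ndarray,
    source_point: np.ndarray,
    target_point: np.ndarray,
    n_segments: int = 100,
    n_fine: int = 2000,
) -> TractSkeleton:
    """Shrink a tract mask to an equal-arc-length centerline with segments.

    The centerline is the shortest path through the voxel graph of the mask
    between the voxels nearest the two endpoints, smoothed with a symmetric
    moving average and resampled at ``n_fine`` equal-arc-length points; the
    ``n_segments`` segments are equal arc-length bins. Each mask voxel is
    assigned to the segment of its nearest centerline sample (nearest-point
    ties resolve to the lower segment index via the ordered KD-tree query).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise GeometryError("empty tract mask")
    source_point = np.asarray(source_point, float)
    target_point = np.asarray(target_point, float)
    # canonical endpoint order: the centerline and voxel assignment are
    # computed once per unordered endpoint pair, then re-oriented, so
    # swapping source and target reverses the profile exactly
    flipped = tuple(source_point) > tuple(target_point)
    a, b = (target_point, source_point) if flipped else (source_point, target_point)
    labeled, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    graph, idx, lin = _mask_graph(mask, affine)
    world = _world_coords(idx, affine)
    src = int(np.argmin(np.linalg.norm(world - a, axis=1)))
    tgt = int(np.argmin(np.linalg.norm(world - b, axis=1)))
    comp_src = labeled[tuple(idx[src])]
    comp_tgt = labeled[tuple(idx[tgt])]
    if comp_src != comp_tgt:
        raise GeometryError(
            f"mask disconnected between endpoints: components {comp_src} vs {comp_tgt} "
            f"of {n_comp}"
        )
    dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
    if not np.isfinite(dist[tgt]):
        raise GeometryError("no path between endpoints inside the mask")
    path = [tgt]
    while path[-1] != src:
        path.append(pred[path[-1]])
    path = np.array(path[::-1])
    line = _smooth_polyline(world[path])
    fine = _resample_equal_arc(line, n_fine)
    seg_steps = np.linalg.norm(np.diff(fine, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_steps)])
    total = arc[-1]
    boundaries = np.linspace(0.0, total, n_segments + 1)
    seg_of_fine = np.minimum(
        np.searchsorted(boundaries, arc, side="right") - 1, n_segments - 1
    ) + 1
    tree = cKDTree(fine)
    _, nearest = tree.query(_world_coords(np.argwhere(mask), affine))
    seg_of_voxel = seg_of_fine[nearest]
    if flipped:
        seg_of_voxel = n_segments + 1 - seg_of_voxel
        fine = fine[::-1].copy()
        arc = total - arc[::-1]
        boundaries = total - boundaries[::-1]
    assignment = {
        tuple(ijk): int(s) for ijk, s in zip(np.argwhere(mask), seg_of_voxel)
    }
    return TractSkeleton(
        centerline=fine,
        arc_length=arc,
        segment_boundaries=boundaries,
        voxel_assignment=assignment,
        n_segments=n_segments,
        mask=mask,
        affine=affine,
    )


def segment_profiles(skel: TractSkeleton, md: VolumeSet) -> pd.DataFrame:
    """Subjects x segments mean MD over assigned voxels; empty segments NaN."""
    if md.shape != skel.mask.shape:
        raise ParameterError("MD grid does not match skeleton grid")
    assign = skel.assignment_volume()
    out = np.full((md.n_subjects, skel.n_segments), np.nan)
    for seg in range(1, skel.n_segments + 1):
        sel = assign == seg
        if sel.any():
            out[:, seg - 1] = md.data[:, sel].mean(axis=1)
    return pd.DataFrame(out, columns=[f"segment_{s:03d}" for s in range(1, skel.n_segments + 1)])


@dataclass
class AlongTractResult:
    """Per-segment GLM statistics ordered source -> target."""

    t: np.ndarray
    z: np.ndarray
    p: np.ndarray
    df: int
    predictor: str
    n_segments: int
    landmarks: dict | None = None  # label -> (first_segment, last_segment)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "segment": np.arange(1, self.n_segments + 1),
                "t": self.t,
                "z": self.z,
                "p": self.p,
            }
        )
        frame["landmark"] = ""
        for label, (lo, hi) in (self.landmarks or {}).items():
            frame.loc[(frame.segment >= lo) & (frame.segment <= hi), "landmark"] = label
        return frame


def along_tract_glm(
    profiles: pd.DataFrame,
    table: pd.DataFrame,
    predictor: str = "upsit",
    covariates=("age", "sex", "smoking"),
    landmarks: dict | None = None,
) -> AlongTractResult:
    """Per-segment GLM of mean MD on the odor-identification predictor."""
    if len(profiles) != len(table):
        raise ParameterError("profiles and table have different subject counts")
    pred_vals = table[predictor].to_numpy(float) if predictor in table else None
    if pred_vals is not None and np.ptp(pred_vals) == 0:
        raise ParameterError(f"predictor {predictor!r} is constant")
    Y = profiles.to_numpy(dtype=float)
    n_segments = Y.shape[1]
    missing = np.isnan(Y).any(axis=0)
    if missing.mean() > 0.5:
        raise ParameterError(
            f"{missing.sum()}/{n_segments} segments missing (>50%); refused"
        )
    design: DesignMatrix = build_design(table, predictor=predictor, covariates=covariates)
    t = np.full(n_segments, np.nan)
    z = np.full(n_segments, np.nan)
    p = np.full(n_segments, np.nan)
    ok = ~missing
    t_ok, df, _, _ = ols_t(design.values, Y[:, ok], design.predictor_index)
    z_ok, _ = t_to_z(t_ok, df)
    t[ok], z[ok], p[ok] = t_ok, z_ok, two_sided_p_from_t(t_ok, df)
    return AlongTractResult(
        t=t, z=z, p=p, df=df, predictor=predictor,
        n_segments=n_segments, landmarks=landmarks,
    )
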