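"""PCA-derived odorant biomarkers from bipartite odorant x voxel networks.

The association between each of the 40 odorant identification items and
every tau (and amyloid) voxel is summarized as a Z statistic, forming a
40 x (V_tau + V_amyloid) matrix. PCA over the odorant dimension yields
components — linear combinations of odorants maximizing the explained
association variance — whose weights score individual subjects and whose
scores can be projected back to voxel maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .imaging_io import ODORANT_COLUMNS, DesignMatrix, VolumeSet, build_design
from .voxel_assoc import ClusterResult, StatMap, cluster_correct, fit_voxel_glm

logger = logging.getLogger(__name__)


@dataclass
class OdorantAssocMatrix:
    """40 odorants x concatenated voxel blocks of association Z statistics."""

    values: np.ndarray  # (40, V_total); NaN rows where the odorant map is undefined
    column_blocks: list  # e.g. [("tau", V_tau), ("amyloid", V_amy)]
    missing_rows: list = field(default_factory=list)

    @property
    def n_odorants(self) -> int:
        return self.values.shape[0]


def build_assoc_matrix(
    table: pd.DataFrame,
    volume_blocks,
    covariates=("age", "sex", "apoe4", "smoking"),
) -> OdorantAssocMatrix:
    """Row k = Z map of the GLM with odorant-k identification as predictor.

    ``volume_blocks`` maps block names to :class:`VolumeSet` objects (e.g.
    ``{"tau": tau_vol, "amyloid": amy_vol}``; the longitudinal variant passes
    a single ``{"tau_diff": ...}`` block of follow-up-minus-baseline voxels).
    Odorants identified by everyone or by no one have undefined group maps:
    their rows are NaN and flagged in ``missing_rows``.
    """
    blocks = list(volume_blocks.items())
    if not blocks:
        raise ParameterError("at least one volume block required")
    widths = [int(v.mask.sum()) for _, v in blocks]
    V_total = sum(widths)
    out = np.full((40, V_total), np.nan)
    missing = []
    for k, col in enumerate(ODORANT_COLUMNS):
        resp = table[col].to_numpy()
        if resp.min() == resp.max():
            missing.append(k)
            logger.info("odorant %s constant in sample; row flagged missing", col)
            continue
        row = []
        for _, vol in blocks:
            design = build_design(table, predictor=col, covariates=covariates)
            row.append(fit_voxel_glm(vol, design).z)
        out[k] = np.concatenate(row)
    return OdorantAssocMatrix(
        values=out,
        column_blocks=[(name, w) for (name, _), w in zip(blocks, widths)],
        missing_rows=missing,
    )


@dataclass
class OdorantComponent:
    """One PCA component: 40 odorant loadings with unit L2 norm."""

    weights: np.ndarray
    variance_explained: float
    component_index: int
    sign_flipped: bool


def pca_components(matrix: OdorantAssocMatrix, n_components: int = 3) -> list:
    """SVD of the centered association matrix over the odorant dimension.

    Columns (voxels) are centered across odorants; no voxel scaling is
    applied since Z statistics are already variance stabilized. Missing
    odorant rows are mean-imputed (zero after centering) so they carry no
    weight. Each component is sign-flipped so its largest-|weight| odorant
    has a positive weight.
    """
    M = matrix.values.copy()
    n_valid = matrix.n_odorants - len(matrix.missing_rows)
    if n_valid < 2:
        raise ParameterError("need at least 2 non-missing odorant rows for PCA")
    valid = np.ones(matrix.n_odorants, bool)
    valid[matrix.missing_rows] = False
    M[~valid] = M[valid].mean(axis=0)
    M = M - M.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    total = (S**2).sum()
    comps = []
    for k in range(min(n_components, len(S))):
        w = U[:, k]
        flip = w[np.argmax(np.abs(w))] < 0
        if flip:
            w = -w
        comps.append(
            OdorantComponent(
                weights=w,
                variance_explained=float(S[k] ** 2 / total) if total > 0 else 0.0,
                component_index=k,
                sign_flipped=bool(flip),
            )
        )
    return comps


def select_components(components, variance_threshold: float = 0.3) -> list:
    """Smallest leading set of components explaining >= the threshold."""
    out, cum = [], 0.0
    for c in components:
        out.append(c)
        cum += c.variance_explained
        if cum >= variance_threshold:
            break
    return out


@dataclass
class DysfunctionScore:
    """Per-subject scalar: weighted combination of odorant responses."""

    scores: np.ndarray
    component_index: int
    centered: bool


def score_subjects(
    component: OdorantComponent, table: pd.DataFrame, center: bool = True
) -> DysfunctionScore:
    """score_i = sum_k w_k * response_ik (responses centered by default)."""
    resp = table[ODORANT_COLUMNS].to_numpy(dtype=float)
    if center:
        resp = resp - resp.mean(axis=0, keepdims=True)
    return DysfunctionScore(
        scores=resp @ component.weights,
        component_index=component.component_index,
        centered=center,
    )


def backproject(
    score: DysfunctionScore,
    vol: VolumeSet,
    table: pd.DataFrame,
    covariates=("age", "sex", "apoe4", "smoking"),
    adjust_for: dict | None = None,
    fwhm_est: float | None = None,
    voxel_p: float = 0.05,
    n_iter: int = 10000,
    seed: int | None = None,
) -> tuple:
    """Voxel-wise GLM of the volume on the dysfunction score.

    ``adjust_for`` may add extra per-subject covariate vectors (e.g. the
    other PET modality's global value). Returns ``(StatMap, ClusterResult)``
    when ``fwhm_est`` is given, else ``(StatMap, None)``.
    """
    extra = {"dysfunction_score": score.scores}
    extra.update(adjust_for or {})
    design: DesignMatrix = build_design(
        table, predictor="dysfunction_score", covariates=covariates, extra=extra
    )
    smap: StatMap = fit_voxel_glm(vol, design)
    result: ClusterResult | None = None
    if fwhm_est is not None:
        result = cluster_correct(
            smap, fwhm_est=fwhm_est, voxel_p=voxel_p, n_iter=n_iter, seed=seed
        )
    return smap, result


def loadings_table(components) -> pd.DataFrame:
    """Odorant x component loading table (the circle-plot analogue)."""
    data = {f"component_{c.component_index + 1}": c.weights for c in components}
    frame = pd.DataFrame(data, index=ODORANT_COLUMNS)
    frame.loc["variance_explained"] = [c.variance_explained for c in components]
    return frame
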