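"""Volumes, atlases, subject tables and GLM design matrices.

This module is the plumbing every analysis stage shares: NIfTI input/output
through nibabel, the in-memory :class:`VolumeSet` container (subjects stacked
on a common grid with an analysis mask), regional-mean extraction against an
integer-labeled :class:`RegionAtlas`, and design-matrix construction from a
subject table.

Subject tables are plain pandas DataFrames with documented columns:

====================  =======================================================
column                meaning
====================  =======================================================
subject_id            unique string id
age                   years
sex                   0/1 (0 = female, 1 = male)
apoe4                 0/1 APOE epsilon-4 carrier
smoking               0/1 smoking history
education             years of education
interval              years between baseline and follow-up scans
odor_01 .. odor_40    binary odorant identification responses
upsit                 composite 0-40, always the sum of the 40 responses
pacc_baseline         cognitive composite, z units
pacc_followup         cognitive composite at follow-up, z units
====================  =======================================================
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import AlignmentError, AtlasError, DesignError, SchemaError

logger = logging.getLogger(__name__)

ODORANT_COLUMNS = [f"odor_{k:02d}" for k in range(1, 41)]
COVARIATE_COLUMNS = ["age", "sex", "apoe4", "smoking", "education", "interval"]


def validate_subject_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the subject-table schema and its invariants.

    Raises :class:`SchemaError` on missing columns, non-binary responses, or
    composites that are not the sum of the 40 responses.
    """
    required = ["subject_id", "age", "sex", "apoe4", "smoking", "education"]
    missing = [c for c in required + ODORANT_COLUMNS + ["upsit"] if c not in table.columns]
    if missing:
        raise SchemaError(f"subject table missing columns: {missing[:5]}...")
    resp = table[ODORANT_COLUMNS].to_numpy()
    if not np.isin(resp, [0, 1]).all():
        raise SchemaError("odorant responses must be binary 0/1")
    sums = resp.sum(axis=1)
    if not np.array_equal(sums, table["upsit"].to_numpy()):
        raise SchemaError("upsit must equal the sum of the 40 odorant responses")
    if (table["upsit"] < 0).any() or (table["upsit"] > 40).any():
        raise SchemaError("upsit outside [0, 40]")
    return table


@dataclass
class VolumeSet:
    """Aligned per-subject 3D volumes with grid geometry and analysis mask.

    ``data`` has shape (n_subjects, nx, ny, nz); ``mask`` is a boolean
    (nx, ny, nz) array restricting every statistic to in-mask voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[1:] != self.mask.shape:
            raise AlignmentError(
                f"data grid {self.data.shape[1:]} != mask grid {self.mask.shape}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def masked(self) -> np.ndarray:
        """(n_subjects, V) matrix of in-mask voxel values."""
        return self.data[:, self.mask]

    def unmask(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a (V,) vector back into a 3D volume."""
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = values
        return out


def default_mask(data: np.ndarray) -> np.ndarray:
    """Analysis mask: voxels finite in every subject with nonzero variance."""
    finite = np.isfinite(data).all(axis=0)
    var = np.zeros(data.shape[1:])
    var[finite] = data[:, finite].var(axis=0)
    return finite & (var > 0)


def read_volumes(paths, mask_policy: str = "auto") -> VolumeSet:
    """Stack NIfTI volumes from ``paths`` into a :class:`VolumeSet`.

    mask_policy: "auto" (finite + nonzero-variance, the default), or "all"
    (every finite voxel).
    """
    imgs = [nib.load(str(p)) for p in paths]
    ref = imgs[0]
    for p, img in zip(paths, imgs):
        if img.shape != ref.shape or not np.allclose(img.affine, ref.affine, atol=1e-4):
            raise AlignmentError(f"grid of {p} does not match {paths[0]}")
    data = np.stack([np.asarray(img.get_fdata(), dtype=float) for img in imgs])
    if mask_policy == "auto":
        mask = default_mask(data)
    elif mask_policy == "all":
        mask = np.isfinite(data).all(axis=0)
    else:
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    return VolumeSet(data=data, affine=np.asarray(ref.affine), mask=mask)


def write_volumes(vol: VolumeSet, paths) -> None:
    """Write each subject volume of ``vol`` as a NIfTI-1 file."""
    if len(paths) != vol.n_subjects:
        raise ValueError("one output path per subject required")
    for i, p in enumerate(paths):
        nib.Nifti1Image(vol.data[i].astype(np.float32), vol.affine).to_filename(str(p))


def write_map(values3d: np.ndarray, affine: np.ndarray, path) -> None:
    nib.Nifti1Image(np.asarray(values3d, np.float32), affine).to_filename(str(path))


@dataclass
class RegionAtlas:
    """Integer-labeled parcellation; 0 is background, labels >= 1 are regions."""

    labels: np.ndarray
    affine: np.ndarray
    names: dict  # label -> region name
    hemisphere: dict = field(default_factory=dict)  # label -> "L"/"R"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = set(self.names) - present
        if missing:
            raise AtlasError(f"named labels absent from atlas volume: {sorted(missing)}")

    @property
    def region_names(self) -> list:
        return [self.names[k] for k in sorted(self.names)]

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise AtlasError(f"unknown region {name!r}")


def regional_means(vol: VolumeSet, atlas: RegionAtlas, apply_mask: bool = True) -> pd.DataFrame:
    """Subjects x regions within-label means.

    Regions with zero in-mask voxels are returned as NaN with a warning.
    """
    if atlas.labels.shape != vol.shape:
        raise AlignmentError("atlas grid does not match volume grid")
    out = {}
    for lab in sorted(atlas.names):
        sel = atlas.labels == lab
        if apply_mask:
            sel = sel & vol.mask
        if not sel.any():
            warnings.warn(f"region {atlas.names[lab]} has no in-mask voxels", stacklevel=2)
            out[atlas.names[lab]] = np.full(vol.n_subjects, np.nan)
        else:
            out[atlas.names[lab]] = vol.data[:, sel].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class DesignMatrix:
    """Named design matrix; the predictor of interest is one column."""

    frame: pd.DataFrame
    predictor: str

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list:
        return list(self.frame.columns)

    @property
    def predictor_index(self) -> int:
        return self.columns.index(self.predictor)


def _collinear_columns(X: np.ndarray, names) -> list:
    """Name columns involved in an (approximate) linear dependence."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [n for n, b in zip(names, bad) if b]


def build_design(
    table: pd.DataFrame,
    predictor,
    covariates=(),
    extra: dict | None = None,
    add_intercept: bool = True,
) -> DesignMatrix:
    """Assemble intercept + covariates + predictor-of-interest design.

    ``predictor`` and ``covariates`` name columns of ``table``; ``extra`` maps
    additional column names to per-subject vectors (e.g. a derived dysfunction
    score, or another modality's global value). Columns are entered on their
    native scale (binary 0/1, years): the partial statistics downstream are
    scale invariant.
    """
    extra = dict(extra or {})
    requested = list(covariates) + [predictor]
    dup = {c for c in requested if requested.count(c) > 1} | (set(extra) & set(covariates))
    if dup:
        raise DesignError(f"duplicate design columns requested: {sorted(dup)}")
    cols = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(table))
    for c in covariates:
        if c in extra:
            continue
        if c not in table.columns:
            raise DesignError(f"covariate {c!r} not in table")
        cols[c] = table[c].to_numpy(dtype=float)
    for name, vec in extra.items():
        cols[name] = np.asarray(vec, dtype=float)
        if cols[name].shape != (len(table),):
            raise DesignError(f"extra column {name!r} has wrong length")
    if predictor in extra:
        pass
    elif predictor in table.columns:
        cols[predictor] = table[predictor].to_numpy(dtype=float)
    else:
        raise DesignError(f"predictor {predictor!r} not in table")
    frame = pd.DataFrame(cols, index=table.index)
    X = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, frame.columns)
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")
    return DesignMatrix(frame=frame, predictor=predictor)
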