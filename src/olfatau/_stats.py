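"""Vectorized OLS across many outcomes and the T->Z transform.

Every mass-univariate stage (voxel-wise GLM, along-tract GLM, odorant
association rows) funnels through :func:`ols_t` so that degrees of freedom,
degenerate-variance handling and the sign-preserving Z transform are defined
in exactly one place.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .exceptions import DesignError

# |Z| cap: scipy's normal quantile saturates around 37.5 for p ~ 1e-308.
Z_CAP = 37.5


def ols_t(X: np.ndarray, Y: np.ndarray, col: int):
    """Fit Y[:, v] ~ X by OLS for every column v; return stats for one column.

    Parameters
    ----------
    X : (n, p) design matrix, full column rank.
    Y : (n, V) outcomes, one column per voxel/segment.
    col : index of the predictor of interest in ``X``.

    Returns
    -------
    t : (V,) t statistics (np.inf where residual variance is exactly 0).
    df : residual degrees of freedom n - p.
    beta : (p, V) coefficient matrix.
    resid : (n, V) residuals.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more observations ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    # exact fits leave only rounding error: treat them as zero residual
    scale = np.einsum("nv,nv->v", Y, Y) / n + 1.0
    exact = sigma2 <= 1e-24 * scale
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[col, col], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[col] / se
    t = np.where(exact | (se == 0.0), np.sign(beta[col]) * np.inf, t)
    return t, df, beta, resid


def t_to_z(t: np.ndarray, df: int):
    """Sign-preserving normal-quantile transform of the two-sided t p-value.

    Returns ``(z, capped)`` where ``capped`` flags entries whose p-value
    underflowed (including exact fits with t = +/-inf); those are reported at
    ``Z_CAP`` with the sign of t.
    """
    t = np.asarray(t, dtype=float)
    p_half = stats.t.sf(np.abs(t), df)  # one tail
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p_half)
    z = np.sign(t) * z
    capped = ~np.isfinite(z) | (np.abs(z) > Z_CAP)
    z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)
    z = np.where(capped, np.sign(np.nan_to_num(t, posinf=1, neginf=-1)) * Z_CAP, z)
    return z, capped


def two_sided_p_from_t(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def partial_corr_precision(data: np.ndarray):
    """All-pairs partial correlations given all remaining variables.

    ``data`` is (n, k); returns the (k, k) matrix with entry (i, j) equal to
    the partial correlation of columns i and j given every other column,
    computed from the precision matrix (pseudo-inverse for stability).
    """
    c = np.corrcoef(data, rowvar=False)
    prec = np.linalg.pinv(c)
    d = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
    pc = -prec / d
    np.fill_diagonal(pc, 1.0)
    return pc


def partial_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None):
    """Partial correlation of x and y given the columns of Z.

    Uses the precision matrix of [x, y, Z] (Schur-complement route). The
    residualize-then-correlate identity is deliberately *not* used here so the
    test suite can keep it as an independent oracle.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if Z is None or (hasattr(Z, "size") and Z.size == 0) or (isinstance(Z, (list, tuple)) and not Z):
        r = np.corrcoef(x, y)[0, 1]
        return float(r)
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[0] != x.shape[0]:
        Z = Z.T
    data = np.column_stack([x, y, Z])
    return float(partial_corr_precision(data)[0, 1])


def partial_corr_pvalue(r: float, n: int, n_cond: int) -> float:
    """Two-sided p-value for a partial correlation via the t distribution."""
    df = n - 2 - n_cond
    if df <= 0:
        return np.nan
    r = np.clip(r, -1.0, 1.0)
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt(df / denom)
    return float(2.0 * stats.t.sf(abs(t), df))


def fisher_z_pvalue(r: float, n: int, n_cond: int) -> float:
    """Two-sided p-value of a (partial) correlation by Fisher's z transform."""
    df = n - n_cond - 3
    if df <= 0:
        return np.nan
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    stat = np.sqrt(df) * abs(np.arctanh(r))
    return float(2.0 * stats.norm.sf(stat))
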