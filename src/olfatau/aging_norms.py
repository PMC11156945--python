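"""Normative modeling of odor identification versus age.

A quadratic normative curve is fit with RANSAC (random minimal subsets, the
consensus model being the one with the most inliers within a fixed band of
score points), subjects are scored as deviations from the curve, and
per-odorant identification rates summarize item difficulty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .imaging_io import ODORANT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class RansacFit:
    """Consensus quadratic fit score = a0 + a1*age + a2*age^2."""

    coeffs: np.ndarray  # (a0, a1, a2)
    inlier_mask: np.ndarray
    threshold: float
    n_iter: int
    sample_size: int
    seed: int | None
    best_iteration: int
    n_skipped: int
    refit: bool

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())

    def predict(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        a0, a1, a2 = self.coeffs
        return a0 + a1 * a + a2 * a**2


def _quad_fit(ages: np.ndarray, scores: np.ndarray) -> np.ndarray:
    V = np.column_stack([np.ones_like(ages), ages, ages**2])
    coef, _, rank, _ = np.linalg.lstsq(V, scores, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("singular quadratic fit")
    return coef


def fit_ransac_quadratic(
    ages,
    scores,
    n_iter: int = 5000,
    sample_size: int = 20,
    threshold: float = 6.0,
    seed: int | None = None,
    refit: bool = True,
) -> RansacFit:
    """RANSAC quadratic fit of composite score on age.

    Each iteration least-squares-fits a quadratic on ``sample_size`` random
    subjects and counts inliers (|observed - predicted| <= threshold over the
    whole sample). The model with the most inliers wins (ties go to the first
    iteration found, under the seeded RNG). By default the returned
    coefficients are refit on the consensus inlier set and the inlier mask is
    recomputed under that final model, so the mask and coefficients are always
    mutually consistent. Iterations with singular subset fits (e.g. repeated
    ages) are skipped and counted in ``n_skipped``.
    """
    ages = np.asarray(ages, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = len(ages)
    if n < sample_size:
        raise ParameterError(f"need >= sample_size={sample_size} subjects, got {n}")
    if not np.isfinite(ages).all() or not np.isfinite(scores).all():
        raise ParameterError("ages and scores must be finite")
    rng = np.random.default_rng(seed)
    best_count, best_coef, best_it, skipped = -1, None, -1, 0
    for it in range(n_iter):
        idx = rng.choice(n, size=sample_size, replace=False)
        try:
            coef = _quad_fit(ages[idx], scores[idx])
        except np.linalg.LinAlgError:
            skipped += 1
            logger.debug("iteration %d skipped: singular subset fit", it)
            continue
        resid = scores - (coef[0] + coef[1] * ages + coef[2] * ages**2)
        count = int((np.abs(resid) <= threshold).sum())
        if count > best_count:
            best_count, best_coef, best_it = count, coef, it
    if best_coef is None:
        raise ParameterError("all RANSAC iterations degenerate")
    inliers = np.abs(scores - np.polyval(best_coef[::-1], ages)) <= threshold
    coeffs = best_coef
    if refit and inliers.sum() >= 3:
        coeffs = _quad_fit(ages[inliers], scores[inliers])
        inliers = np.abs(scores - np.polyval(coeffs[::-1], ages)) <= threshold
    return RansacFit(
        coeffs=np.asarray(coeffs),
        inlier_mask=inliers,
        threshold=threshold,
        n_iter=n_iter,
        sample_size=sample_size,
        seed=seed,
        best_iteration=best_it,
        n_skipped=skipped,
        refit=refit,
    )


def deviation_scores(fit: RansacFit, ages, scores) -> np.ndarray:
    """Observed minus predicted score; negative = worse than the age norm."""
    return np.asarray(scores, dtype=float) - fit.predict(ages)


def odorant_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-odorant identification fractions with their sort order.

    Returns a DataFrame indexed by odorant column with columns ``rate`` and
    ``rank`` (1 = most identified), preserving the instrument item order in
    the index.
    """
    rates = table[ODORANT_COLUMNS].mean(axis=0)
    ranks = rates.rank(ascending=False, method="first").astype(int)
    return pd.DataFrame({"rate": rates, "rank": ranks})
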