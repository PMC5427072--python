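"""Voxelwise brain–behavior correlation and the critical-r threshold.

Correlates a stack of per-subject maps (ReHo or fALFF) with a behavioral
score (SSRT), optionally partialling out a covariate (age) via the
first-order partial-correlation identity

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

with df = n - 2 for the full correlation and n - 3 with one covariate.
The voxelwise significance threshold is the critical r derived from the
t distribution: r_crit = t_crit / sqrt(t_crit^2 + df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .maps import BrainMap

__all__ = [
    "CorrelationMap",
    "voxelwise_correlation",
    "voxelwise_partial_correlation",
    "critical_r",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    """Voxelwise correlation coefficients with their df bookkeeping."""

    r_values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    n_subjects: int
    n_covariates: int
    kind: str  # e.g. "reho_ssrt", "falff_ssrt", "conjunction_r"

    @property
    def df(self) -> int:
        return self.n_subjects - 2 - self.n_covariates

    def as_brain_map(self) -> BrainMap:
        kind = "conjunction_r" if self.kind == "conjunction_r" else "r"
        return BrainMap(self.r_values, self.mask, self.affine, kind=kind)


def _stack(map_stack: Sequence[BrainMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(map_stack) < 3:
        raise ValueError("need at least 3 subjects")
    first = map_stack[0]
    for m in map_stack[1:]:
        if m.values.shape != first.values.shape or not np.array_equal(m.mask, first.mask):
            raise ValueError("all maps must share grid and mask")
    x = np.stack([m.values for m in map_stack], axis=0)  # (S, X, Y, Z)
    return x, first.mask, first.affine


def _pearson_stack(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each voxel's subject vector and the score vector.

    Voxels with zero variance (or any non-finite subject value) come back
    NaN.
    """
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    xc = x - x.mean(axis=0)
    xnorm = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("s...,s->...", xc, yc) / (xnorm * ynorm)
    return r


def voxelwise_correlation(
    map_stack: Sequence[BrainMap], scores: np.ndarray, kind: str = "r"
) -> CorrelationMap:
    """Full Pearson correlation of a map stack against subject scores."""
    x, mask, affine = _stack(map_stack)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (x.shape[0],):
        raise ValueError("scores length must equal the number of maps")
    if scores.std() == 0:
        raise ValueError("score vector is constant")
    r = _pearson_stack(x, scores)
    r[~mask] = np.nan
    return CorrelationMap(r, mask, affine, n_subjects=len(scores), n_covariates=0, kind=kind)


def voxelwise_partial_correlation(
    map_stack: Sequence[BrainMap],
    scores: np.ndarray,
    covariate: np.ndarray,
    kind: str = "r",
) -> CorrelationMap:
    """Age-adjusted (first-order partial) correlation, df = n - 3.

    Voxels collinear with the covariate (|r_xz| = 1) are undefined and
    counted in a log warning.
    """
    x, mask, affine = _stack(map_stack)
    scores = np.asarray(scores, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if scores.shape != (x.shape[0],) or covariate.shape != (x.shape[0],):
        raise ValueError("scores/covariate length must equal the number of maps")
    if covariate.std() == 0:
        raise ValueError("covariate is constant")
    r_xy = _pearson_stack(x, scores)
    r_xz = _pearson_stack(x, covariate)
    r_yz = float(stats.pearsonr(scores, covariate)[0])
    if abs(r_yz) >= 1 - 1e-12:
        raise ValueError("scores and covariate are collinear")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    collinear = mask & np.isfinite(r_xz) & (np.abs(r_xz) >= 1 - 1e-12)
    if collinear.any():
        logger.warning(
            "voxelwise_partial_correlation: %d voxels collinear with covariate",
            int(collinear.sum()),
        )
        r[collinear] = np.nan
    r[~mask] = np.nan
    return CorrelationMap(r, mask, affine, n_subjects=len(scores), n_covariates=1, kind=kind)


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Scalar first-order partial correlation r_xy.z (closed form)."""
    r_xy = float(stats.pearsonr(x, y)[0])
    r_xz = float(stats.pearsonr(x, z)[0])
    r_yz = float(stats.pearsonr(y, z)[0])
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def critical_r(alpha: float, df: int, tails: int = 2) -> float:
    """Smallest |r| significant at level ``alpha`` with ``df`` degrees of freedom.

    Inverts the t test of a correlation coefficient:
    t = r * sqrt(df / (1 - r^2)), so r_crit = t_crit / sqrt(t_crit^2 + df).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    t_crit = stats.t.ppf(1 - alpha / tails, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))
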