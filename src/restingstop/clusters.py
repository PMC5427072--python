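"""Cluster-extent inference: Monte-Carlo minimum cluster size and thresholding.

The Monte-Carlo procedure (AlphaSim-style) estimates how large a cluster
of supra-threshold voxels must be before it is unlikely to arise from a
smooth null field: each iteration generates Gaussian white noise on the
grid, smooths it with the analysis FWHM, standardizes within the mask,
applies the two-tailed voxel threshold, labels connected components, and
records the largest cluster. The minimum extent k_min is the smallest k
whose exceedance frequency P(max null cluster >= k) drops to the
corrected alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .correlate import CorrelationMap

__all__ = [
    "ConnectivityRule",
    "MCThresholdResult",
    "label_clusters",
    "alphasim_kmin",
    "apply_threshold",
    "cluster_table",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ConnectivityRule:
    """3-D connectivity: 6 (faces), 18 (+edges) or 26 (+corners) neighbors."""

    neighbors: int = 26

    def __post_init__(self) -> None:
        if self.neighbors not in _STRUCTURES:
            raise ValueError("neighbors must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, _STRUCTURES[self.neighbors])


@dataclass
class MCThresholdResult:
    """Monte-Carlo minimum cluster extent and its null distribution.

    ``k_min`` is None when no extent can reach the corrected level
    (e.g. voxel_alpha = 1 floods the mask every iteration).
    """

    k_min: int | None
    voxel_alpha: float
    corrected_alpha: float
    n_iterations: int
    fwhm_mm: float
    max_cluster_null: np.ndarray
    seed: int
    connectivity: int = 26

    @property
    def attainable(self) -> bool:
        return self.k_min is not None

    def exceedance_prob(self, k: int) -> float:
        """Empirical P(max null cluster size >= k)."""
        return float((self.max_cluster_null >= k).mean())


def label_clusters(
    binary_map: np.ndarray, rule: ConnectivityRule = ConnectivityRule()
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a binary map; labels dense from 1.

    Returns (labeled map, size array) where sizes[i] is the voxel count of
    cluster label i+1.
    """
    labeled, n = ndimage.label(np.asarray(binary_map, dtype=bool), structure=rule.structure)
    sizes = np.bincount(labeled.ravel(), minlength=n + 1)[1:]
    return labeled, sizes


def _max_null_cluster(
    z: np.ndarray, mask: np.ndarray, z_crit: float, structure: np.ndarray
) -> int:
    """Largest two-tailed supra-threshold cluster (|z| >= z_crit) in a null field."""
    labeled, n = ndimage.label((np.abs(z) >= z_crit) & mask, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def alphasim_kmin(
    mask: np.ndarray,
    fwhm_mm: float,
    voxel_alpha: float,
    corrected_alpha: float,
    *,
    voxel_mm: float = 2.0,
    rule: ConnectivityRule = ConnectivityRule(),
    n_iterations: int = 1000,
    seed: int = 0,
) -> MCThresholdResult:
    """Monte-Carlo estimate of the minimum cluster extent.

    Per iteration: white noise on the grid -> Gaussian smoothing at
    ``fwhm_mm`` -> standardization within the mask -> two-tailed voxel
    threshold at ``voxel_alpha`` -> connected-component labeling (each sign
    separately) -> record the maximum cluster size. k_min is the smallest
    k with empirical P(max >= k) <= corrected_alpha.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if not (0 < voxel_alpha <= 1):
        raise ValueError("voxel_alpha must lie in (0, 1]")
    if not (0 < corrected_alpha < 1):
        raise ValueError("corrected_alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1 - voxel_alpha / 2) if voxel_alpha < 1 else 0.0
    sigma_vox = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / voxel_mm
    structure = rule.structure
    maxima = np.empty(n_iterations, dtype=int)
    for i in range(n_iterations):
        noise = rng.standard_normal(mask.shape)
        if sigma_vox > 0:
            noise = ndimage.gaussian_filter(noise, sigma_vox, mode="constant")
        vals = noise[mask]
        z = (noise - vals.mean()) / vals.std()
        maxima[i] = _max_null_cluster(z, mask, z_crit, structure)

    n_in_mask = int(mask.sum())
    k_min: int | None = None
    for k in range(1, int(maxima.max()) + 2):
        if (maxima >= k).mean() <= corrected_alpha:
            k_min = k
            break
    if k_min is not None and k_min > n_in_mask:
        k_min = None
    return MCThresholdResult(
        k_min=k_min,
        voxel_alpha=voxel_alpha,
        corrected_alpha=corrected_alpha,
        n_iterations=n_iterations,
        fwhm_mm=fwhm_mm,
        max_cluster_null=maxima,
        seed=seed,
        connectivity=rule.neighbors,
    )


def cluster_table(
    values: np.ndarray,
    labeled: np.ndarray,
    sizes: np.ndarray,
    affine: np.ndarray,
    k_min: int,
    sign: str,
) -> pd.DataFrame:
    """Summarize surviving clusters: size, peak world-mm coordinate, peak r."""
    rows = []
    for lbl, size in enumerate(sizes, start=1):
        if size < k_min:
            continue
        in_cluster = labeled == lbl
        vals = np.where(in_cluster, values, np.nan)
        flat = np.nanargmin(vals) if sign == "negative" else np.nanargmax(np.abs(vals))
        ijk = np.unravel_index(flat, values.shape)
        world = affine @ np.array([*ijk, 1.0])
        rows.append(
            {
                "cluster_id": lbl,
                "size_voxels": int(size),
                "peak_x_mm": float(world[0]),
                "peak_y_mm": float(world[1]),
                "peak_z_mm": float(world[2]),
                "peak_r": float(values[ijk]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "size_voxels", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_r"],
    )
    if len(table):
        table = table.sort_values("size_voxels", ascending=False, ignore_index=True)
        table["cluster_id"] = np.arange(1, len(table) + 1)
    return table


def apply_threshold(
    corr_map: CorrelationMap,
    r_crit: float,
    k_min: int | None,
    sign: str = "negative",
    rule: ConnectivityRule = ConnectivityRule(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Voxel + extent threshold a correlation map.

    Keeps voxels with r beyond ``r_crit`` in the requested sign, labels
    each sign separately, drops clusters smaller than ``k_min`` (an
    unattainable k_min of None drops everything), and returns the
    thresholded map (NaN where nothing survives) plus a cluster table.
    """
    if sign not in ("negative", "positive", "both"):
        raise ValueError("sign must be 'negative', 'positive' or 'both'")
    r = corr_map.r_values
    defined = corr_map.mask & np.isfinite(r)
    masks = []
    if sign in ("negative", "both"):
        masks.append(("negative", defined & (r <= -r_crit)))
    if sign in ("positive", "both"):
        masks.append(("positive", defined & (r >= r_crit)))

    out = np.full(r.shape, np.nan)
    tables = []
    for sgn, binary in masks:
        labeled, sizes = label_clusters(binary, rule)
        if k_min is None:
            continue
        for lbl, size in enumerate(sizes, start=1):
            if size >= k_min:
                sel = labeled == lbl
                out[sel] = r[sel]
        tables.append(cluster_table(r, labeled, sizes, corr_map.affine, k_min, sgn))
    if tables:
        table = pd.concat(tables, ignore_index=True)
        if len(table):
            table = table.sort_values("size_voxels", ascending=False, ignore_index=True)
            table["cluster_id"] = np.arange(1, len(table) + 1)
    else:
        table = cluster_table(r, np.zeros_like(r, dtype=int), np.array([], dtype=int),
                              corr_map.affine, 1, sign)
    return out, table
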