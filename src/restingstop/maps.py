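"""Local functional-connectivity maps: ReHo and fALFF.

ReHo (regional homogeneity) assigns to each voxel the Kendall coefficient
of concordance (KCC, Kendall's W) of its time series together with its
neighbors in a 27-voxel cube (7- and 19-voxel neighborhoods are also
supported). With K series of length n and R_i the rank sum across series
at time point i,

    W = (sum_i R_i^2 - n * Rbar^2) / (K^2 (n^3 - n) / 12),   Rbar = K(n+1)/2.

Ties get mid-ranks with no tie-correction factor — the original ReHo
convention; with continuous data ties are measure-zero anyway.

fALFF (fractional amplitude of low-frequency fluctuations) is the sum of
FFT amplitudes (square root of the power spectrum) over 0.01–0.08 Hz
divided by the sum over the broader 0.01–0.25 Hz range, computed on the
detrended but NOT band-passed series. Frequency bins are half-open
[low, high) on the FFT grid and the DC bin is always excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .prep import VolumeSeries

__all__ = ["BrainMap", "SpectralBands", "kcc", "reho_map", "falff_map", "standardize_map"]

logger = logging.getLogger(__name__)

MAP_KINDS = ("reho", "falff", "r", "conjunction_r")


@dataclass
class BrainMap:
    """3-D scalar map on a masked grid; NaN marks undefined voxels."""

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}")

    def in_mask(self) -> np.ndarray:
        """Finite in-mask values, flattened."""
        v = self.values[self.mask]
        return v[np.isfinite(v)]


@dataclass(frozen=True)
class SpectralBands:
    """Numerator and denominator amplitude bands for fALFF, in Hz."""

    num_low_hz: float = 0.01
    num_high_hz: float = 0.08
    den_low_hz: float = 0.01
    den_high_hz: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.num_low_hz < self.num_high_hz):
            raise ValueError("invalid numerator band")
        if not (0 <= self.den_low_hz < self.den_high_hz):
            raise ValueError("invalid denominator band")
        if self.num_low_hz < self.den_low_hz or self.num_high_hz > self.den_high_hz:
            raise ValueError("numerator band must lie inside the denominator band")


def kcc(series_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K time series over n points.

    Returns W in [0, 1]; 1 means all K series share the same rank ordering
    over time. Raises on a constant series (ranking undefined without a
    tie rule carrying all the weight).
    """
    m = np.asarray(series_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a K x n matrix with K >= 2 and n >= 2")
    if np.any(m.std(axis=1) == 0):
        raise ValueError("constant series: KCC undefined")
    k, n = m.shape
    ranks = stats.rankdata(m, axis=1)
    r_i = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2.0
    s = float(np.sum((r_i - rbar) ** 2))
    w = 12.0 * s / (k**2 * (n**3 - n))
    return float(min(max(w, 0.0), 1.0))


def _neighborhood_offsets(neighborhood: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        order = sum(abs(v) for v in d)
        if neighborhood == 7 and order > 1:
            continue
        if neighborhood == 19 and order > 2:
            continue
        offs.append(d)
    return offs


def _shift_sum(arr: np.ndarray, offsets: list[tuple[int, int, int]]) -> np.ndarray:
    """Sum of zero-padded spatial shifts of ``arr`` (3-D or 4-D) over offsets."""
    out = np.zeros_like(arr)
    shape = arr.shape[:3]
    for dx, dy, dz in offsets:
        src = []
        dst = []
        for d, size in zip((dx, dy, dz), shape):
            src.append(slice(max(0, -d), size - max(0, d)))
            dst.append(slice(max(0, d), size - max(0, -d)))
        out[tuple(dst)] += arr[tuple(src)]
    return out


def reho_map(series: VolumeSeries, neighborhood: int = 27) -> BrainMap:
    """Per-voxel KCC of each in-mask voxel with its neighbors.

    The input should already be band-pass filtered. Neighbors outside the
    mask are dropped (K reduced accordingly); voxels with fewer than 2
    usable series are set undefined and counted in a log warning.
    """
    if neighborhood not in (7, 19, 27):
        raise ValueError("neighborhood must be 7, 19 or 27")
    mask = series.mask
    n = series.n_timepoints
    # ordinal ranks via double argsort; ties (measure-zero on continuous
    # data) are broken by time order instead of mid-ranked
    order = np.argsort(series.data, axis=-1)
    ranks = np.empty(series.data.shape, dtype=np.int32)
    np.put_along_axis(ranks, order, np.arange(1, n + 1, dtype=np.int32), axis=-1)
    ranks *= mask[..., None]
    offsets = _neighborhood_offsets(neighborhood)
    r_sum = _shift_sum(ranks, offsets)  # R_i per voxel per time point
    k_map = _shift_sum(mask.astype(np.int32), offsets).astype(float)

    # sum_i (R_i - Rbar)^2 = sum_i R_i^2 - n * Rbar^2
    sum_sq = np.einsum("...t,...t->...", r_sum, r_sum, dtype=np.int64).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = k_map * (n + 1) / 2.0
        s = sum_sq - n * rbar**2
        denom = k_map**2 * (n**3 - n) / 12.0
        w = s / denom
    undefined = mask & (k_map < 2)
    n_undef = int(undefined.sum())
    if n_undef:
        logger.warning("reho_map: %d in-mask voxels with K < 2 set undefined", n_undef)
    w = np.clip(w, 0.0, 1.0)
    w[~mask | undefined] = np.nan
    return BrainMap(values=w, mask=mask, affine=series.affine, kind="reho")


def falff_map(
    series_unfiltered: VolumeSeries, bands: SpectralBands = SpectralBands()
) -> BrainMap:
    """Fractional low-frequency amplitude per voxel, in [0, 1].

    Input must be detrended but not band-passed (the denominator needs the
    full 0.01–0.25 Hz content). Zero-denominator voxels (identically zero
    series) are undefined and logged.
    """
    s = series_unfiltered
    if bands.den_high_hz > s.nyquist_hz + 1e-12:
        raise ValueError(
            f"denominator band edge {bands.den_high_hz} Hz exceeds Nyquist {s.nyquist_hz} Hz"
        )
    freqs = np.fft.rfftfreq(s.n_timepoints, d=s.tr_s)
    amp = np.abs(np.fft.rfft(s.data, axis=-1))
    num_bins = (freqs >= bands.num_low_hz) & (freqs < bands.num_high_hz) & (freqs > 0)
    den_bins = (freqs >= bands.den_low_hz) & (freqs < bands.den_high_hz) & (freqs > 0)
    num = amp[..., num_bins].sum(axis=-1)
    den = amp[..., den_bins].sum(axis=-1)
    zero_den = s.mask & (den == 0)
    if zero_den.any():
        logger.warning("falff_map: %d in-mask voxels with zero denominator", int(zero_den.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / den
    vals[~s.mask | zero_den] = np.nan
    return BrainMap(values=vals, mask=s.mask, affine=s.affine, kind="falff")


def standardize_map(brain_map: BrainMap) -> BrainMap:
    """Divide by the within-mask mean so the in-mask mean becomes 1."""
    mean = float(np.nanmean(brain_map.values[brain_map.mask]))
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"within-mask mean must be positive, got {mean}")
    return BrainMap(
        values=brain_map.values / mean,
        mask=brain_map.mask,
        affine=brain_map.affine,
        kind=brain_map.kind,
    )
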