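"""Minimum-statistic conjunction of two negative correlation maps.

Because the interest is in *negative* brain-behavior correlations, the
minimum-statistic conjunction takes the voxelwise MAXIMUM of the two raw
(unthresholded) r maps: a voxel survives a negative threshold only if
BOTH parents lie beyond it, i.e. the conjunction carries the weaker of
the two pieces of evidence. The conjunction map is then cluster-corrected
with the same Monte-Carlo extent procedure as its parents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clusters import ConnectivityRule, MCThresholdResult, apply_threshold
from .correlate import CorrelationMap

__all__ = ["conjunction_max_r", "conjunction_inference"]


def conjunction_max_r(map1: CorrelationMap, map2: CorrelationMap) -> CorrelationMap:
    """Voxelwise maximum of two raw correlation maps (negative conjunction).

    Parents must share grid, mask, subject count and covariate set.
    Voxels undefined in either parent are undefined in the conjunction.
    """
    if map1.r_values.shape != map2.r_values.shape:
        raise ValueError("correlation maps have different grids")
    if not np.array_equal(map1.mask, map2.mask):
        raise ValueError("correlation maps have different masks")
    if map1.n_subjects != map2.n_subjects or map1.n_covariates != map2.n_covariates:
        raise ValueError("correlation maps have different n/df bookkeeping")
    values = np.maximum(map1.r_values, map2.r_values)  # NaN propagates
    return CorrelationMap(
        r_values=values,
        mask=map1.mask,
        affine=map1.affine,
        n_subjects=map1.n_subjects,
        n_covariates=map1.n_covariates,
        kind="conjunction_r",
    )


def conjunction_inference(
    conj: CorrelationMap,
    r_crit: float,
    mc: MCThresholdResult,
    rule: ConnectivityRule = ConnectivityRule(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold the conjunction at -r_crit and apply the extent k_min."""
    return apply_threshold(conj, r_crit, mc.k_min, sign="negative", rule=rule)
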