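"""Ground-truth LAI from destructive sampling and validation statistics.

The destructive reference ("leaf length x width" method) measures every
leaf of n sample plants with a ruler and converts the summed length x width
products to true leaf area through a shape factor f obtained from one
representative cut plant:

    f = (sum of true single-leaf areas) / (sum of len * wid)
    S = f * mean_plant( sum_leaves len * wid )      [single-plant leaf area]
    L = S * N                                       [N plants per m^2]

Estimates (photographic system, LAI2000 canopy analyzer, MODIS windows) are
compared against this truth with ordinary least squares and RMSE statistics.
Because the printed campaign results do not state which RMSE convention was
used, both are reported: the RMSE of the signed errors and the residual
RMSE sqrt(SSE/(n-2)) of the fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlantSample",
    "ComparisonStats",
    "shape_factor",
    "lai_llw",
    "comparison_stats",
    "modis_window_mean",
]


@dataclass
class PlantSample:
    """Leaf measurements of one plant: (length, width) pairs in metres.

    ``measured_leaf_areas`` holds true single-leaf areas (m^2) for the
    representative cut plant used to derive the shape factor.
    """

    leaves: Sequence[tuple[float, float]]
    measured_leaf_areas: Optional[Sequence[float]] = None

    def sum_len_wid(self) -> float:
        if len(self.leaves) == 0:
            raise ValueError("plant has no leaves")
        total = 0.0
        for ln, wd in self.leaves:
            if ln <= 0 or wd <= 0:
                raise ValueError("leaf length and width must be positive")
            total += ln * wd
        return total


def shape_factor(rep_plant: PlantSample) -> float:
    """Shape factor f = sum(true areas) / sum(len * wid) of the cut plant.

    f is 1 for rectangular leaves and below 1 for convex tapered leaves;
    values outside (0, 1.2] are suspicious for corn and trigger a warning.
    """
    areas = rep_plant.measured_leaf_areas
    if areas is None or len(areas) == 0:
        raise ValueError("representative plant needs measured leaf areas")
    if len(areas) != len(rep_plant.leaves):
        raise ValueError("areas and leaf measurements must align")
    if any(a <= 0 for a in areas):
        raise ValueError("measured leaf areas must be positive")
    f = float(sum(areas) / rep_plant.sum_len_wid())
    if not 0.0 < f <= 1.2:
        import warnings

        warnings.warn(
            f"shape factor {f:.3f} outside the plausible range (0, 1.2]",
            stacklevel=2,
        )
    return f


def lai_llw(field_plants: Iterable[PlantSample], f_shape: float, N: float) -> float:
    """Destructive LAI: L = S * N with S = f * mean plant sum(len * wid)."""
    if N <= 0:
        raise ValueError("plant density N must be positive")
    if f_shape <= 0:
        raise ValueError("shape factor must be positive")
    sums = [p.sum_len_wid() for p in field_plants]
    if not sums:
        raise ValueError("need at least one field plant")
    S = f_shape * float(np.mean(sums))
    return S * N


@dataclass
class ComparisonStats:
    """OLS and error statistics of estimates against reference truth.

    ``slope``/``intercept`` come from regressing the estimate on the truth;
    ``rmse_error`` is sqrt(mean(signed error^2)); ``rmse_residual`` is the
    regression residual RMSE sqrt(SSE/(n-2)).  ``relative_errors`` uses the
    truth as denominator; ``unstable_relative`` flags records with truth
    below 0.2 where relative error is not meaningful.
    """

    n: int
    slope: float
    intercept: float
    r_value: float
    rmse_error: float
    rmse_residual: float
    max_abs_error: float
    bias: float
    relative_errors: np.ndarray
    unstable_relative: np.ndarray


def comparison_stats(truth, estimate) -> ComparisonStats:
    """Compare estimates with reference truth (paired arrays)."""
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("truth and estimate must be equal-length 1-D arrays")
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 pairs for residual RMSE")
    if np.ptp(t) == 0:
        raise ValueError("constant truth: regression undefined")
    lr = stats.linregress(t, e)
    resid = e - (lr.intercept + lr.slope * t)
    err = e - t
    with np.errstate(divide="ignore"):
        rel = np.abs(err) / t
    return ComparisonStats(
        n=n,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r_value=float(lr.rvalue),
        rmse_error=float(np.sqrt(np.mean(err**2))),
        rmse_residual=float(np.sqrt(np.sum(resid**2) / (n - 2))),
        max_abs_error=float(np.max(np.abs(err))),
        bias=float(np.mean(err)),
        relative_errors=rel,
        unstable_relative=t < 0.2,
    )


def modis_window_mean(values) -> float:
    """Arithmetic mean of a 3x3 satellite LAI window (exactly 9 values)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size != 9:
        raise ValueError(f"a 3x3 window needs 9 values, got {arr.size}")
    if np.any(np.isnan(arr)):
        raise ValueError("window contains missing values")
    return float(arr.mean())
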