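"""Dose sampling, cumulative DVH construction, and DVH dose metrics.

Conventions
-----------
* Doses are sampled at voxel centers by trilinear interpolation of the
  dose grid.
* D_Mean is the arithmetic mean of the sampled doses.
* The near-maximum dose D_p% (default p = 2%) is the minimum dose inside
  the hottest p% of the volume, computed as an order statistic: with
  n sampled voxels, the k-th largest dose where k = ceil(p * n).  No
  interpolation is involved, so the metric is exact and exactly
  homogeneous under dose rescaling.  (Planning systems often interpolate
  a binned DVH instead; this dialect is deliberate and documented.)
* Metrics are always computed from raw sampled doses — the DVH bin width
  only affects exported curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from rtcohort.geometry import BinaryMask
from rtcohort.rt_model import DoseGrid, ValidationError

log = logging.getLogger(__name__)

#: fraction of mask voxels allowed to fall outside the dose grid before
#: the sampling is considered a data-integrity failure
MAX_OUTSIDE_FRACTION = 0.05


class DoseSamplingError(ValidationError):
    """Raised when dose cannot be sampled where required."""


@dataclass
class DVHCurve:
    """Cumulative DVH: % of structure volume receiving >= each dose level."""

    dose_axis: np.ndarray  # Gy, ascending
    volume_fraction: np.ndarray  # %, non-increasing, 100 -> 0

    def v_at(self, dose: float) -> float:
        """Volume % receiving at least ``dose`` (exact, from the curve grid)."""
        idx = np.searchsorted(self.dose_axis, dose, side="right") - 1
        return float(self.volume_fraction[max(idx, 0)])


@dataclass
class DoseMetrics:
    d_mean: float  # Gy
    d_2pct: float  # Gy
    pd: float  # Gy, prescribed dose used for normalization


def _interpolator(dose_grid: DoseGrid) -> RegularGridInterpolator:
    g = dose_grid.grid
    return RegularGridInterpolator(
        (g.z_centers, g.y_centers, g.x_centers),
        np.asarray(dose_grid.values, float),
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )


def sample_dose(dose_grid: DoseGrid, point) -> float:
    """Trilinear dose (Gy) at an (x, y, z) mm point inside the grid."""
    x, y, z = (float(v) for v in point)
    val = _interpolator(dose_grid)([[z, y, x]])[0]
    if math.isnan(val):
        raise DoseSamplingError(f"point ({x}, {y}, {z}) mm outside dose grid")
    return float(val)


def voxel_doses(mask: BinaryMask, dose_grid: DoseGrid) -> np.ndarray:
    """Sampled dose (Gy) at each foreground voxel center of ``mask``.

    Up to :data:`MAX_OUTSIDE_FRACTION` of the voxels may fall outside the
    dose grid (clinical dose grids often crop); those are dropped with a
    logged count.  More than that raises :class:`DoseSamplingError`.
    """
    if mask.n_voxels == 0:
        raise ValidationError("voxel_doses of empty mask")
    pts = mask.grid.voxel_centers(mask.voxels)
    vals = _interpolator(dose_grid)(pts[:, [2, 1, 0]])
    outside = np.isnan(vals)
    n_out = int(outside.sum())
    if n_out > MAX_OUTSIDE_FRACTION * len(vals):
        raise DoseSamplingError(
            f"{n_out}/{len(vals)} mask voxels outside dose grid (> {MAX_OUTSIDE_FRACTION:.0%})"
        )
    if n_out:
        log.warning("dropped %d/%d mask voxels outside dose grid", n_out, len(vals))
    return vals[~outside]


def cumulative_dvh(doses: np.ndarray, bin_width: float = 0.01) -> DVHCurve:
    """Exact empirical survival curve on a bin grid of the given width."""
    doses = np.asarray(doses, float)
    if doses.size == 0:
        raise ValidationError("cumulative_dvh of empty dose list")
    top = float(doses.max())
    n_bins = int(math.floor(top / bin_width)) + 2
    axis = bin_width * np.arange(n_bins)
    # fraction of voxels with dose >= d, exactly
    sorted_doses = np.sort(doses)
    idx = np.searchsorted(sorted_doses, axis, side="left")
    frac = 100.0 * (len(doses) - idx) / len(doses)
    return DVHCurve(dose_axis=axis, volume_fraction=frac)


def d_mean(doses: np.ndarray) -> float:
    """Mean absorbed dose (Gy)."""
    doses = np.asarray(doses, float)
    if doses.size == 0:
        raise ValidationError("d_mean of empty dose list")
    return float(doses.mean())


def d_percent(doses: np.ndarray, p: float = 0.02) -> float:
    """Near-maximum dose D_p%: the k-th largest dose, k = ceil(p * n).

    ``p`` is a fraction in (0, 1]; ``d_percent(d, 1.0)`` is the minimum
    dose and ``p -> 0+`` approaches the maximum.
    """
    doses = np.asarray(doses, float)
    if doses.size == 0:
        raise ValidationError("d_percent of empty dose list")
    if not 0 < p <= 1:
        raise ValidationError(f"p must be in (0, 1], got {p}")
    k = math.ceil(p * doses.size)
    return float(np.partition(doses, doses.size - k)[doses.size - k])


def dose_metrics(doses: np.ndarray, pd: float) -> DoseMetrics:
    return DoseMetrics(d_mean=d_mean(doses), d_2pct=d_percent(doses, 0.02), pd=pd)


def rescale_dose(dose_grid: DoseGrid, planned_fractions: int, delivered_fractions: int) -> DoseGrid:
    """Scale the whole grid by delivered/planned (the cleanup rescale).

    ``delivered_fractions = 0`` zeroes the grid; flagging such courses is
    the caller's (curation/QC) responsibility.
    """
    if planned_fractions < 1:
        raise ValidationError("planned_fractions must be >= 1")
    if delivered_fractions < 0:
        raise ValidationError("delivered_fractions must be >= 0")
    factor = delivered_fractions / planned_fractions
    return DoseGrid(grid=dose_grid.grid, values=np.asarray(dose_grid.values, float) * factor)


def dvh_to_csv(curve: DVHCurve, path) -> None:
    import pandas as pd

    pd.DataFrame({"dose_Gy": curve.dose_axis, "volume_pct": curve.volume_fraction}).to_csv(
        path, index=False
    )
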