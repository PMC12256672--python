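"""Pairwise segmentation comparison and cohort deviation summaries.

An autosegmentation is compared against a manual reference contour with
the standard geometric agreement metrics — Dice similarity coefficient
(DSC), 95th-percentile Hausdorff distance (HD95) and mean surface
distance (MSD) — plus the dosimetric differences in mean dose (D_Mean)
and near-maximum dose (D_2%), expressed as a percentage of the
prescribed dose (PD).

HD95 and MSD are both computed from the *pooled* set of directed
nearest-surface distances (auto -> manual and manual -> auto): MSD is
the mean of that set and HD95 its 95th percentile (linear interpolation
between closest ranks).  Pooling makes both metrics symmetric in their
arguments.

Cohort-level systematic (mu) and random (sigma) dose deviations are the
sample mean and sample standard deviation (n-1 denominator) of the
per-patient dose differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rtcohort import dosimetry, geometry
from rtcohort.geometry import BinaryMask
from rtcohort.rt_model import DoseGrid, Grid3D, Structure, ValidationError


@dataclass
class SegComparison:
    """Agreement between one autosegmentation and its manual reference."""

    dsc: float  # [0, 1]
    hd95: float  # mm
    msd: float  # mm
    dvol_cm3: float  # auto - manual
    ddmean_pct_pd: float  # (auto - manual) D_Mean, % of PD
    dd2_pct_pd: float  # (auto - manual) D_2%, % of PD
    degenerate: bool = False  # both masks empty


@dataclass
class CohortDeviationSummary:
    """Systematic (mu) / random (sigma) deviation of a difference metric."""

    mu: float
    sigma: float
    n: int


def _check_grids(mask_a: BinaryMask, mask_b: BinaryMask) -> None:
    if not mask_a.same_grid(mask_b):
        raise ValidationError("masks live on different grids")


def dsc(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A^B| / (|A| + |B|); 1 if both empty."""
    _check_grids(mask_a, mask_b)
    na, nb = mask_a.n_voxels, mask_b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(mask_a.voxels & mask_b.voxels))
    return 2.0 * inter / (na + nb)


def pooled_surface_distances(mask_a: BinaryMask, mask_b: BinaryMask) -> np.ndarray:
    """Directed nearest-surface distances pooled over both directions."""
    _check_grids(mask_a, mask_b)
    sa = geometry.surface_points(mask_a)
    sb = geometry.surface_points(mask_b)
    return np.concatenate(
        [geometry.directed_distances(sa, sb), geometry.directed_distances(sb, sa)]
    )


def hd95(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """95th percentile of the pooled surface distances (mm)."""
    return float(np.percentile(pooled_surface_distances(mask_a, mask_b), 95))


def msd(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Mean of the pooled surface distances (mm).

    The pooled set is sorted before averaging so the result is exactly
    symmetric in the argument order (float summation is not associative).
    """
    return float(np.mean(np.sort(pooled_surface_distances(mask_a, mask_b))))


def compare(
    auto_structure: Structure,
    manual_structure: Structure,
    ct_grid: Grid3D,
    dose_grid: DoseGrid | None,
    pd: float,
) -> SegComparison:
    """Full geometric + dosimetric comparison on the case's CT grid.

    Dose differences are (auto - manual) / pd * 100; when no dose grid is
    given they are reported as NaN.  Two empty structures yield the
    degenerate comparison (DSC 1, distances 0) with a flag so cohort
    summaries stay visible but unpoisoned.
    """
    mask_auto = geometry.rasterize(auto_structure, ct_grid)
    mask_manual = geometry.rasterize(manual_structure, ct_grid)
    if mask_auto.n_voxels == 0 and mask_manual.n_voxels == 0:
        return SegComparison(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    dvol = geometry.volume_cm3(mask_auto) - geometry.volume_cm3(mask_manual)
    the_dsc = dsc(mask_auto, mask_manual)
    the_hd95 = hd95(mask_auto, mask_manual)
    the_msd = msd(mask_auto, mask_manual)
    ddmean = dd2 = float("nan")
    if dose_grid is not None:
        if pd <= 0:
            raise ValidationError("prescribed dose must be > 0 for dose normalization")
        da = dosimetry.voxel_doses(mask_auto, dose_grid)
        dm = dosimetry.voxel_doses(mask_manual, dose_grid)
        ddmean = (dosimetry.d_mean(da) - dosimetry.d_mean(dm)) / pd * 100.0
        dd2 = (dosimetry.d_percent(da) - dosimetry.d_percent(dm)) / pd * 100.0
    return SegComparison(the_dsc, the_hd95, the_msd, dvol, ddmean, dd2)


_SUMMARY_FIELDS = ("dsc", "hd95", "msd", "dvol_cm3", "ddmean_pct_pd", "dd2_pct_pd")


def summarize(comparisons: list[SegComparison]) -> dict[str, CohortDeviationSummary]:
    """Per-metric systematic/random deviation over a cohort of comparisons."""
    if len(comparisons) < 2:
        raise ValidationError("cohort summary needs n >= 2 comparisons")
    out = {}
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(c, name) for c in comparisons], float)
        out[name] = CohortDeviationSummary(
            mu=float(np.mean(vals)), sigma=float(np.std(vals, ddof=1)), n=len(vals)
        )
    return out


def comparisons_to_frame(rows: dict[tuple[str, str], SegComparison]):
    """Long-format DataFrame (patient, organ, metric, value) for export/plots."""
    import pandas as pd

    records = []
    for (patient, organ), comp in rows.items():
        for name in _SUMMARY_FIELDS:
            records.append(
                {"patient": patient, "organ": organ, "metric": name, "value": getattr(comp, name)}
            )
    return pd.DataFrame.from_records(records)
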