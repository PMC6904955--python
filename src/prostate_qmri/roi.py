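"""ROI handling and longitudinal trajectory extraction.

The three analysis regions are the central gland (CG = prostate minus
peripheral zone), the peripheral zone (PZ), and the tumor.  Each region is
eroded by an isotropic 2 mm margin (Euclidean distance transform on the
1 mm analysis grid) to suppress residual registration error at the region
boundary, then the median of the valid quantitative-map voxels inside the
eroded region is extracted per week.  Per-patient trajectories are
normalized to the pretreatment (week-0) value; missing interior weeks may be
linearly interpolated for display and population medians, but interpolated
points are flagged and never feed significance tests or persistence calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import QuantMap, VolumeGrid

__all__ = [
    "EmptyRoiError",
    "derive_cg",
    "erode_mask",
    "extract_median",
    "normalize_trajectory",
    "interpolate_missing",
    "build_trajectory_table",
]

TRAJECTORY_COLUMNS = [
    "patient",
    "ht",
    "dialect",
    "roi",
    "map_type",
    "week",
    "median_value",
    "normalized_value",
    "measured",
    "interpolated",
]


class EmptyRoiError(ValueError):
    """A derived or eroded region is empty where a non-empty one is required."""


def _as_bool(mask: VolumeGrid | np.ndarray) -> np.ndarray:
    return (mask.data if isinstance(mask, VolumeGrid) else np.asarray(mask)) > 0


def derive_cg(prostate: VolumeGrid, pz: VolumeGrid) -> VolumeGrid:
    """Central gland as the exact set difference prostate AND NOT pz.

    PZ voxels outside the prostate are clipped with a warning (they cannot
    contribute to either compartment); an empty result is an error.
    """
    p = _as_bool(prostate)
    z = _as_bool(pz)
    outside = z & ~p
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} PZ voxels lie outside the prostate; clipping",
            stacklevel=2,
        )
    cg = p & ~z
    if not cg.any():
        raise EmptyRoiError("central gland is empty (PZ covers the whole prostate)")
    ref = prostate if isinstance(prostate, VolumeGrid) else VolumeGrid(p.astype(np.uint8))
    return VolumeGrid(cg.astype(np.uint8), ref.spacing, ref.origin)


def erode_mask(mask: VolumeGrid, margin_mm: float = 2.0) -> VolumeGrid:
    """Keep voxels whose Euclidean distance to the region boundary exceeds the margin.

    Implemented with the Euclidean distance transform using the grid spacing,
    so the margin is exact and isotropic in mm regardless of voxel
    anisotropy.  ``margin_mm=0`` is the identity; the result may be empty
    (thin structures), which callers must handle.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    m = _as_bool(mask)
    if margin_mm == 0 or not m.any():
        return VolumeGrid(m.astype(np.uint8), mask.spacing, mask.origin)
    dt = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    return VolumeGrid((dt > margin_mm).astype(np.uint8), mask.spacing, mask.origin)


def extract_median(qmap: QuantMap, mask: VolumeGrid | np.ndarray) -> float:
    """Median map value over valid voxels inside the mask.

    Uses the standard even-count convention (mean of the two central order
    statistics).  Returns NaN — a missing-value flag, never zero — when the
    mask has no valid voxels.
    """
    m = _as_bool(mask)
    if m.shape != qmap.values.data.shape:
        raise ValueError("mask and map shapes differ")
    vals = qmap.masked_values(m)
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def normalize_trajectory(medians: dict[int, float]) -> dict[int, float]:
    """Divide each weekly median by the week-0 median; week 0 maps to exactly 1.

    Raises if week 0 is absent or non-positive — such series are excluded
    from normalized analysis upstream.
    """
    if 0 not in medians or not np.isfinite(medians[0]):
        raise ValueError("week-0 median missing; cannot normalize")
    base = medians[0]
    if base <= 0:
        raise ValueError("week-0 median must be positive")
    out = {w: float(v) / base for w, v in sorted(medians.items()) if np.isfinite(v)}
    out[0] = 1.0
    return out


def interpolate_missing(
    normalized: dict[int, float], weeks: tuple[int, ...] = tuple(range(6))
) -> tuple[dict[int, float], dict[int, bool]]:
    """Fill interior missing weeks by linear interpolation between measured weeks.

    No extrapolation beyond the last measured week.  Returns the filled
    series and per-week flags marking interpolated points; flagged values are
    for display and population medians only.
    """
    measured = sorted(w for w in normalized if np.isfinite(normalized[w]))
    if len(measured) < 2:
        raise ValueError("interpolation requires at least two measured weeks")
    filled: dict[int, float] = {}
    flags: dict[int, bool] = {}
    lo, hi = measured[0], measured[-1]
    xs = np.array(measured, float)
    ys = np.array([normalized[w] for w in measured], float)
    for w in weeks:
        if w in normalized and np.isfinite(normalized[w]):
            filled[w] = float(normalized[w])
            flags[w] = False
        elif lo < w < hi:
            filled[w] = float(np.interp(w, xs, ys))
            flags[w] = True
        # weeks beyond the measured range are simply absent
    return filled, flags


def build_trajectory_table(median_rows: pd.DataFrame, interpolate: bool = True) -> pd.DataFrame:
    """Assemble the tidy trajectory table from per-week median rows.

    ``median_rows`` needs columns (patient, ht, dialect, roi, map_type, week,
    median_value, measured).  Adds ``normalized_value`` (per patient/roi/map,
    week-0 anchored) and, when requested, linearly interpolated rows for
    interior missing weeks (``measured=False, interpolated=True``).  Series
    without a measured week 0 are dropped (logged via warning): they cannot
    be normalized.
    """
    rows = []
    for (patient, roi, map_type), g in median_rows.groupby(
        ["patient", "roi", "map_type"], sort=True
    ):
        g = g[g["measured"]]
        medians = dict(zip(g["week"].astype(int), g["median_value"].astype(float)))
        medians = {w: v for w, v in medians.items() if np.isfinite(v)}
        meta = g.iloc[0]
        if 0 not in medians:
            warnings.warn(
                f"{patient} {roi} {map_type}: no measured week 0; series excluded",
                stacklevel=2,
            )
            continue
        normalized = normalize_trajectory(medians)
        if interpolate and len(normalized) >= 2:
            filled, flags = interpolate_missing(normalized)
        else:
            filled = normalized
            flags = {w: False for w in normalized}
        for w in sorted(filled):
            rows.append(
                {
                    "patient": patient,
                    "ht": bool(meta["ht"]),
                    "dialect": meta["dialect"],
                    "roi": roi,
                    "map_type": map_type,
                    "week": int(w),
                    "median_value": medians.get(w, float("nan")),
                    "normalized_value": filled[w],
                    "measured": w in medians,
                    "interpolated": flags[w],
                }
            )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
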