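"""Voxelwise quantitative map fitting: mono-exponential ADC and multi-echo T2.

Both maps come from log-linear regression of the signal decay.  The ADC fit
is ordinary least squares of ln S(b) on b over a perfusion-insensitive
b-value subset (never b=0); with exactly two b-values it reduces to the
closed-form two-point estimator.  The T2 fit is weighted least squares of
ln S(TE) on TE with per-voxel weights w_i = S_i^2 — the first-order
variance-stabilizing choice for log-transformed magnitude data, so that
high-signal early echoes dominate and the noise floor of late echoes is
down-weighted.  Unweighted log-linear fitting is available as an alternative
strategy.

Voxels with non-positive signal anywhere in the fitted subset, or estimates
outside the physical plausibility windows (0 < ADC <= 4e-3 mm^2/s,
0 < T2 <= 1000 ms), are marked invalid and excluded from all downstream
statistics.
"""

from __future__ import annotations

import numpy as np

from .grid import AcquisitionSeries, QuantMap, VolumeGrid

__all__ = ["fit_adc", "fit_t2", "select_registration_echo", "ADC_MAX", "T2_MAX_MS"]

ADC_MAX = 4.0e-3  # mm^2/s, upper physical plausibility bound (free water ~3e-3)
T2_MAX_MS = 1000.0  # ms, upper plausibility bound for pelvic soft tissue


def _weighted_linefit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Per-voxel weighted LS of y on x along the last axis; returns (slope, intercept)."""
    sw = w.sum(axis=-1)
    swx = (w * x).sum(axis=-1)
    swy = (w * y).sum(axis=-1)
    swxx = (w * x * x).sum(axis=-1)
    swxy = (w * x * y).sum(axis=-1)
    denom = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swxy - swx * swy) / denom
        intercept = (swy - slope * swx) / sw
    return slope, intercept


def fit_adc(dwi: AcquisitionSeries, b_subset=None) -> QuantMap:
    """Fit a mono-exponential ADC map, S(b) = S0 exp(-b * ADC), by log-linear OLS.

    Parameters
    ----------
    dwi
        DWI series indexed by b-value (s/mm^2); must include the b-values in
        ``b_subset``.
    b_subset
        b-values entering the fit.  Defaults to every available b-value in
        [200, 800] s/mm^2.  b=0 is never allowed (perfusion sensitivity), and
        at least two b-values are required.
    """
    if dwi.kind != "dwi":
        raise ValueError("fit_adc expects a DWI series")
    avail = np.asarray(dwi.index, float)
    if b_subset is None:
        b_subset = tuple(b for b in avail if 200.0 <= b <= 800.0)
    b_subset = np.asarray(sorted(float(b) for b in b_subset))
    if b_subset.size < 2:
        raise ValueError("ADC fitting requires at least two b-values")
    if np.any(b_subset <= 0):
        raise ValueError("b=0 (or negative b) must not enter the ADC fit")
    missing = [b for b in b_subset if not np.isclose(avail, b).any()]
    if missing:
        raise ValueError(f"b-values {missing} not present in series {avail}")

    stack = np.stack([dwi.volume_at(b).data for b in b_subset], axis=-1).astype(np.float64)
    positive = np.all(stack > 0, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    w = np.ones_like(logs)
    slope, intercept = _weighted_linefit(b_subset, logs, w)
    adc = -slope
    valid = positive & np.isfinite(adc) & (adc > 0) & (adc <= ADC_MAX)
    values = np.where(valid, adc, -1.0)
    grid = dwi.grid
    return QuantMap(
        VolumeGrid(values, grid.spacing, grid.origin),
        valid,
        "ADC",
        {"b_values": [float(b) for b in b_subset]},
    )


def fit_t2(echoes: AcquisitionSeries, weighting: str = "iterated-signal") -> QuantMap:
    """Fit a T2 map, S(TE) = S0 exp(-TE/T2), by weighted log-linear regression.

    Weighting strategies:

    ``'iterated-signal'`` (default)
        Two rounds of iteratively reweighted LS: an unweighted log-linear fit
        supplies predicted signals whose squares become the weights of the
        next round.  Using *predicted* rather than measured signals as
        weights avoids the upward T2 bias that noise-correlated weights
        introduce near the Rician floor.
    ``'squared-signal'``
        Single pass with measured-signal-squared weights.
    ``'uniform'``
        Plain log-linear OLS.

    T2 = -1/slope and S0 = exp(intercept); the fitted S0 volume is stored in
    ``fit_meta``.
    """
    if echoes.kind != "echo":
        raise ValueError("fit_t2 expects a multi-echo series")
    te = np.asarray(echoes.index, float)
    if te.size < 3:
        raise ValueError("T2 fitting requires at least three echoes")
    if np.unique(te).size != te.size:
        raise ValueError("duplicate echo times in series")
    if weighting not in ("iterated-signal", "squared-signal", "uniform"):
        raise ValueError(f"unknown weighting strategy {weighting!r}")

    stack = echoes.stack().astype(np.float64)
    positive = np.all(stack > 0, axis=-1)
    safe = np.where(stack > 0, stack, 1.0)
    logs = np.log(safe)
    if weighting == "squared-signal":
        w = safe**2
    else:
        w = np.ones_like(safe)
    slope, intercept = _weighted_linefit(te, logs, w)
    if weighting == "iterated-signal":
        for _ in range(2):
            # weights need no precision: evaluate the predicted decay in
            # float32 with a clipped exponent (guards noise-only voxels)
            expo = (intercept[..., None] + slope[..., None] * te).astype(np.float32)
            pred = np.exp(np.clip(expo, -40.0, 40.0))
            # back to float64: float32 accumulators would contaminate the
            # normal equations
            w = (pred * pred).astype(np.float64)
            slope, intercept = _weighted_linefit(te, logs, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = -1.0 / slope
    s0 = np.exp(intercept)
    valid = positive & np.isfinite(t2) & (t2 > 0) & (t2 <= T2_MAX_MS)
    values = np.where(valid, t2, -1.0)
    grid = echoes.grid
    return QuantMap(
        VolumeGrid(values, grid.spacing, grid.origin),
        valid,
        "T2",
        {
            "echo_times_ms": [float(t) for t in te],
            "weighting": weighting,
            "s0": np.where(valid, s0, -1.0),
        },
    )


def select_registration_echo(
    echoes: AcquisitionSeries, target_te: float = 120.0
) -> VolumeGrid:
    """Pick the echo volume closest in TE to the anatomical T2-weighted echo time.

    Ties break toward the earlier echo (higher signal).
    """
    if len(echoes) == 0:
        raise ValueError("empty echo series")
    te = np.asarray(echoes.index, float)
    best = int(np.argmin(np.abs(te - target_te)))  # argmin takes the first == earlier TE
    return echoes.volumes[best]
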