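"""Preprocessing chain: reflectance -> clean, smoothed daily index series.

The chain mirrors standard practice for daily NBAR-derived vegetation-index
series in sparsely vegetated regions:

1. quality screening — keep only dates where *both* bands carry the accepted
   QA flag (:func:`apply_qa_mask`);
2. two-band enhanced vegetation index, EVI2 = 2.5 (NIR − Red) /
   (NIR + 2.4 Red + 1) (:func:`compute_evi2`);
3. noise floor — EVI2 values ≤ 0.08 are treated as non-vegetated or
   contaminated (cloud shadow, snow, bare soil) and masked
   (:func:`mask_low_vi`);
4. gap filling by an interpolating cubic spline through the remaining valid
   points, limited to gaps of at most ``max_gap_days``
   (:func:`gapfill_spline`);
5. Savitzky–Golay smoothing on the filled series (:func:`smooth_sg`).

Masking happens before gap filling, so the spline never leans on
contaminated observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline, UnivariateSpline
from scipy.signal import savgol_filter

from .series import (
    EmptyInputError,
    InsufficientDataError,
    ReflectanceSeries,
    VISeries,
)

__all__ = [
    "PreprocessConfig",
    "apply_qa_mask",
    "compute_evi2",
    "reflectance_to_evi2",
    "mask_low_vi",
    "gapfill_spline",
    "smooth_sg",
    "preprocess",
]

#: minimum number of valid points for a cubic interpolating spline
_MIN_SPLINE_POINTS = 4


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing chain.

    ``vi_floor`` is the index noise floor (values ≤ floor are masked);
    ``max_gap_days`` caps the gap length the spline may bridge; the SG window
    and polynomial order are in days of the daily grid.
    """

    accepted_qa: int = 0
    vi_floor: float = 0.08
    max_gap_days: int = 60
    sg_window_days: int = 31
    sg_polyorder: int = 2


def apply_qa_mask(series: ReflectanceSeries, accepted_flag: int = 0) -> ReflectanceSeries:
    """Invalidate dates whose QA flag differs from ``accepted_flag`` on either band.

    Values are never altered, only the validity mask.
    """
    if len(series) == 0:  # pragma: no cover - constructor already forbids
        raise EmptyInputError("empty reflectance series")
    good = (np.asarray(series.qa_nir) == accepted_flag) & (
        np.asarray(series.qa_red) == accepted_flag
    )
    return series.with_valid(series.valid & good)


def compute_evi2(nir, red):
    """Two-band enhanced vegetation index.

    EVI2 = 2.5 (NIR − Red) / (NIR + 2.4 Red + 1).  Vectorises elementwise;
    non-finite inputs or a non-positive denominator yield NaN rather than
    raising.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + 2.4 * red + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 2.5 * (nir - red) / denom
    bad = ~np.isfinite(nir) | ~np.isfinite(red) | (denom <= 0)
    out = np.where(bad, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def reflectance_to_evi2(series: ReflectanceSeries) -> VISeries:
    """Compute EVI2 on valid dates and place it on a contiguous daily grid."""
    vi = compute_evi2(series.nir, series.red)
    vi = np.where(series.valid, vi, np.nan)
    return VISeries.from_observations(series.dates, vi, kind="EVI2")


def mask_low_vi(series: VISeries, floor: float = 0.08) -> VISeries:
    """Mask index values at or below the noise floor (inclusive ≤)."""
    with np.errstate(invalid="ignore"):
        keep = series.values > floor
    return series.with_values(series.values, valid=series.valid & keep)


def _gap_runs(valid: np.ndarray):
    """Yield (start, stop) index pairs of maximal invalid runs (stop exclusive)."""
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _noise_scale(t: np.ndarray, v: np.ndarray) -> float:
    """Robust noise SD from first differences of day-adjacent valid samples."""
    adjacent = np.diff(t) == 1.0
    d = np.diff(v)[adjacent]
    if d.size < 8:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / math.sqrt(2.0)


def gapfill_spline(series: VISeries, max_gap_days: int = 60) -> VISeries:
    """Fill short gaps with a cubic univariate spline through valid points.

    Only interior gaps of at most ``max_gap_days`` days are filled; longer
    gaps and the unobserved flanks stay invalid, and originally valid values
    are returned bit-identical.  The spline's smoothing parameter is set
    from a robust estimate of the day-to-day noise (median absolute first
    difference), so noiseless series are interpolated exactly while a noisy
    series is bridged by a smooth curve instead of an oscillating exact
    interpolant — a cubic forced through every noisy daily sample can swing
    inside a gap by several times the seasonal amplitude.

    Raises
    ------
    InsufficientDataError
        If fewer than four valid points are available (cubic spline order).
    """
    nvalid = series.n_valid
    if nvalid < _MIN_SPLINE_POINTS:
        raise InsufficientDataError(
            f"need >= {_MIN_SPLINE_POINTS} valid points for cubic gap filling, "
            f"got {nvalid}"
        )
    t = np.arange(len(series), dtype=float)
    vmask = series.valid
    sigma = _noise_scale(t[vmask], series.values[vmask])
    if sigma > 0.0:
        spline = UnivariateSpline(
            t[vmask], series.values[vmask], k=3, s=nvalid * sigma**2, ext="const"
        )
    else:
        spline = InterpolatedUnivariateSpline(
            t[vmask], series.values[vmask], k=3, ext="const"
        )
    values = series.values.copy()
    valid = vmask.copy()
    first, last = np.flatnonzero(vmask)[[0, -1]]
    for start, stop in _gap_runs(vmask):
        if start <= first or stop > last:  # flank, not an interior gap
            continue
        if stop - start > max_gap_days:
            continue
        values[start:stop] = spline(t[start:stop])
        valid[start:stop] = True
    values[~valid] = np.nan
    return series.with_values(values, valid=valid)


def _valid_runs(valid: np.ndarray):
    """Yield (start, stop) of maximal valid runs (stop exclusive)."""
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def smooth_sg(series: VISeries, window_days: int = 31, polyorder: int = 2) -> VISeries:
    """Savitzky–Golay smoothing on each contiguous valid run.

    Runs shorter than the window are left untouched; invalid spans are never
    touched.  Raises :class:`InsufficientDataError` if no run is at least the
    window length.
    """
    if window_days % 2 == 0 or window_days < 3:
        raise ValueError("window_days must be an odd integer >= 3")
    if polyorder >= window_days:
        raise ValueError("polyorder must be smaller than window_days")
    values = series.values.copy()
    any_run = False
    for start, stop in _valid_runs(series.valid):
        if stop - start < window_days:
            continue
        any_run = True
        values[start:stop] = savgol_filter(
            series.values[start:stop], window_days, polyorder, mode="interp"
        )
    if not any_run:
        raise InsufficientDataError(
            f"no contiguous valid run of at least {window_days} days"
        )
    return series.with_values(values)


def preprocess(series: VISeries, config: PreprocessConfig | None = None) -> VISeries:
    """Run floor masking, spline gap filling and SG smoothing in order."""
    cfg = config or PreprocessConfig()
    out = mask_low_vi(series, floor=cfg.vi_floor)
    out = gapfill_spline(out, max_gap_days=cfg.max_gap_days)
    out = smooth_sg(out, window_days=cfg.sg_window_days, polyorder=cfg.sg_polyorder)
    return out
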