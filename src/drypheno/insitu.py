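"""In-situ validation phenology from camera GCC and flux-tower GPP.

Near-surface cameras record 30-minute RGB digital numbers; the green
chromatic coordinate GCC = G/(R+G+B) tracks canopy greenness.  Daily series
are built as the 90th percentile of each day's GCC values (robust to
illumination changes and shadows), smoothed with the same Savitzky–Golay
filter as the satellite index, and seasons are extracted with the same
detector but a 20% side-amplitude threshold, which captures the subtler
seasonal dynamics of continuous GCC/GPP records better than the 50% level
used for the satellite index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seasons import PhenoRecord, SeasonConfig, retrieve_pheno
from .series import EmptyInputError, VISeries

__all__ = [
    "CameraSeries",
    "compute_gcc",
    "daily_composite_gcc",
    "prepare_gpp",
    "retrieve_insitu_pheno",
    "filter_site_years",
]


@dataclass(frozen=True)
class CameraSeries:
    """30-minute mean RGB digital numbers for one camera region of interest."""

    timestamps: pd.DatetimeIndex
    red_dn: np.ndarray
    green_dn: np.ndarray
    blue_dn: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        if len(ts) == 0:
            raise EmptyInputError("camera series is empty")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)
        for name in ("red_dn", "green_dn", "blue_dn"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(ts),):
                raise ValueError(f"{name} must have length {len(ts)}")
            if np.nanmin(arr) < 0:
                raise ValueError("digital numbers must be non-negative")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.timestamps)


def compute_gcc(red_dn, green_dn, blue_dn):
    """Green chromatic coordinate G/(R+G+B); NaN where all channels are zero."""
    r = np.asarray(red_dn, dtype=float)
    g = np.asarray(green_dn, dtype=float)
    b = np.asarray(blue_dn, dtype=float)
    total = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        gcc = g / total
    gcc = np.where(total > 0, gcc, np.nan)
    return float(gcc) if gcc.ndim == 0 else gcc


def daily_composite_gcc(series: CameraSeries, min_obs_per_day: int = 6) -> VISeries:
    """Daily 90th-percentile GCC composite.

    Days with fewer than ``min_obs_per_day`` finite GCC observations are
    invalid.  The percentile uses the linear-interpolation convention between
    order statistics, pinned so composites are bit-reproducible.
    """
    gcc = compute_gcc(series.red_dn, series.green_dn, series.blue_dn)
    df = pd.DataFrame({"day": series.timestamps.normalize(), "gcc": gcc}).dropna()
    if df.empty:
        raise EmptyInputError("no finite GCC observations")
    agg = df.groupby("day")["gcc"].agg(
        value=lambda x: float(np.percentile(x, 90.0)), count="size"
    )
    agg.loc[agg["count"] < min_obs_per_day, "value"] = np.nan
    return VISeries.from_observations(agg.index, agg["value"].to_numpy(), kind="GCC")


def prepare_gpp(dates, gpp) -> VISeries:
    """Daily GPP series; negative values (partitioning artifacts) are masked."""
    values = np.asarray(list(gpp), dtype=float)
    values = np.where(values < 0, np.nan, values)
    return VISeries.from_observations(dates, values, kind="GPP")


def retrieve_insitu_pheno(
    series: VISeries,
    target_year: int,
    threshold_fraction: float = 0.2,
    config: SeasonConfig | None = None,
) -> PhenoRecord:
    """Season retrieval for in-situ series (20% side-amplitude threshold).

    The input must already be daily (camera GCC composited) and SG-smoothed;
    the season structure is identical to the satellite retrieval.
    """
    cfg = config or SeasonConfig(threshold_fraction=threshold_fraction)
    return retrieve_pheno(
        series,
        target_year,
        threshold_fraction=threshold_fraction,
        config=cfg,
    )


def filter_site_years(
    table: pd.DataFrame,
    min_completeness: float = 0.75,
    allowed_camera_types: tuple[str, ...] = ("I",),
    excluded_landcover: tuple[str, ...] = ("EBF", "ENF"),
) -> pd.DataFrame:
    """Screen a site-year metadata table for validation use.

    Expects (a subset of) columns ``completeness`` (fraction of the year with
    data), ``camera_type`` and ``landcover``; rules for absent columns are
    skipped.  Evergreen forests are excluded by default because neither
    camera greenness nor the satellite index shows a usable seasonal cycle
    there.
    """
    out = table
    if "completeness" in out.columns:
        out = out[out["completeness"] >= min_completeness]
    if "camera_type" in out.columns:
        out = out[out["camera_type"].isin(allowed_camera_types)]
    if "landcover" in out.columns:
        out = out[~out["landcover"].isin(excluded_landcover)]
    return out.reset_index(drop=True)
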