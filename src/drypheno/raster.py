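"""Per-pixel raster processing, masks, aggregation and GeoTIFF products.

Phenology rasters are written one file per (year, metric, season) under the
naming scheme ``GDPD_<year>_<SOS|EOS>_<season1|season2>.tif`` with DOY values
as signed 16-bit integers (nodata −32768).  DOY may fall outside [1, 365]
for seasons straddling the year boundary; SOS/EOS are rounded to the nearest
day at export while tabular output keeps the fractional dates.

GeoTIFF georeferencing is written and read through standard tags
(ModelPixelScale, ModelTiepoint, GDAL nodata) via :mod:`tifffile`; the CRS
is carried as a free-form string.  Only axis-aligned north-up grids are
supported — reprojection is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .preprocess import PreprocessConfig, preprocess
from .seasons import SeasonConfig, retrieve_pheno
from .series import DryphenoError, InsufficientDataError, VISeries
from .validate import retrieval_ratio

__all__ = [
    "RasterGrid",
    "PhenoRaster",
    "NODATA",
    "run_raster",
    "write_pheno_raster",
    "read_pheno_raster",
    "pheno_raster_filename",
    "apply_dryland_mask",
    "apply_landcover_mask",
    "aggregate_temporal",
    "aggregate_spatial",
]

NODATA = -32768

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class RasterGrid:
    """Axis-aligned raster geometry: origin of the top-left corner, cell size.

    ``dy`` is negative for north-up rasters (row index increases southwards).
    """

    x0: float
    y0: float
    dx: float
    dy: float
    crs: str = ""

    def __post_init__(self) -> None:
        if self.dx == 0 or self.dy == 0:
            raise ValueError("cell sizes must be nonzero")


@dataclass(frozen=True)
class PhenoRaster:
    """One phenology metric raster: integer DOY per pixel, nodata −32768."""

    grid: RasterGrid
    metric: str  # "SOS" | "EOS"
    season: int  # 1 | 2
    year: int
    values: np.ndarray  # (ny, nx) int16
    nodata: int = NODATA

    def __post_init__(self) -> None:
        if self.metric not in ("SOS", "EOS"):
            raise ValueError("metric must be 'SOS' or 'EOS'")
        if self.season not in (1, 2):
            raise ValueError("season must be 1 or 2")
        values = np.asarray(self.values)
        if values.dtype != np.int16:
            values = values.astype(np.int16)
        object.__setattr__(self, "values", values)


def pheno_raster_filename(year: int, metric: str, season: int) -> str:
    """Product naming scheme: GDPD_<year>_<metric>_<season>.tif."""
    return f"GDPD_{year}_{metric}_season{season}.tif"


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_pheno_raster(raster: PhenoRaster, path) -> Path:
    """Write a PhenoRaster as a single-band LZW GeoTIFF."""
    path = Path(path)
    grid = raster.grid
    description = json.dumps(
        {
            "crs": grid.crs,
            "metric": raster.metric,
            "season": raster.season,
            "year": raster.year,
        }
    )
    nodata_ascii = str(raster.nodata) + "\x00"
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(grid.dx), abs(grid.dy), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0), True),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii, True),
    ]
    tifffile.imwrite(
        path,
        raster.values,
        compression="lzw",
        description=description,
        extratags=extratags,
    )
    return path


def read_pheno_raster(path) -> PhenoRaster:
    """Read a phenology GeoTIFF written by :func:`write_pheno_raster`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = int(float(tags[_TAG_GDAL_NODATA].value.rstrip("\x00")))
        meta = json.loads(tags["ImageDescription"].value)
    grid = RasterGrid(
        x0=float(tie[3]),
        y0=float(tie[4]),
        dx=float(scale[0]),
        dy=-float(scale[1]),
        crs=meta.get("crs", ""),
    )
    return PhenoRaster(
        grid=grid,
        metric=meta["metric"],
        season=int(meta["season"]),
        year=int(meta["year"]),
        values=values.astype(np.int16),
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# masks


def apply_dryland_mask(ai: np.ndarray, threshold: float = 0.65) -> np.ndarray:
    """Dryland mask: True where the aridity index is strictly below 0.65."""
    ai = np.asarray(ai, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(ai) & (ai < threshold)


def apply_landcover_mask(
    lc_rasters: Sequence[np.ndarray],
    excluded_classes: set,
    require_stable: bool = True,
) -> np.ndarray:
    """True where the class is allowed in every year and (optionally) stable."""
    if len(lc_rasters) == 0:
        raise ValueError("need at least one land-cover raster")
    stack = np.stack([np.asarray(r) for r in lc_rasters])
    allowed = np.ones(stack.shape[1:], dtype=bool)
    for cls in excluded_classes:
        allowed &= ~np.any(stack == cls, axis=0)
    if require_stable and len(lc_rasters) > 1:
        allowed &= np.all(stack == stack[0], axis=0)
    return allowed


# ---------------------------------------------------------------------------
# aggregation (resolution-degradation experiment)


def aggregate_temporal(
    series: VISeries, step_days: int = 16, stat: str = "mean"
) -> VISeries:
    """Composite a daily series into ``step_days`` bins, then back to daily.

    Bins are non-overlapping windows counted from Jan-01 of the first year
    in the series; the bin value is the mean (or max) of its valid days and
    is stamped at the bin midpoint.  The composited points are linearly
    re-interpolated to the daily grid so the same daily season detector can
    run on the degraded series.
    """
    if stat not in ("mean", "max"):
        raise ValueError("stat must be 'mean' or 'max'")
    origin = pd.Timestamp(year=series.dates[0].year, month=1, day=1)
    offsets = ((series.dates - origin) / pd.Timedelta(days=1)).astype(int)
    bins = offsets // step_days
    df = pd.DataFrame(
        {"bin": bins, "value": np.where(series.valid, series.values, np.nan)}
    )
    agg = df.groupby("bin")["value"].agg(stat if stat == "max" else "mean")
    agg = agg.dropna()
    if len(agg) < 2:
        raise InsufficientDataError("fewer than two valid composite bins")
    mid = origin + pd.to_timedelta((agg.index.to_numpy() + 0.5) * step_days, unit="D")
    mid_days = (mid - series.dates[0]) / pd.Timedelta(days=1)
    t = np.arange(len(series), dtype=float)
    daily = np.interp(t, mid_days, agg.to_numpy(), left=np.nan, right=np.nan)
    return series.with_values(daily, valid=np.isfinite(daily))


def aggregate_spatial(stack: np.ndarray, factor: int) -> np.ndarray:
    """Block-average a (t, ny, nx) stack by ``factor``, ignoring NaN pixels."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    t, ny, nx = stack.shape
    if ny % factor or nx % factor:
        raise ValueError("factor must divide both raster dimensions")
    blocks = stack.reshape(t, ny // factor, factor, nx // factor, factor)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=(2, 4))


# ---------------------------------------------------------------------------
# per-pixel pipeline


def run_raster(
    stack: np.ndarray,
    dates: pd.DatetimeIndex,
    grid: RasterGrid,
    years: Sequence[int],
    mask: np.ndarray | None = None,
    out_dir=None,
    preprocess_config: PreprocessConfig | None = None,
    season_config: SeasonConfig | None = None,
) -> dict:
    """Run the full retrieval per pixel over a daily index stack.

    ``stack`` is (time, row, col) with NaN marking missing observations;
    ``mask`` (row, col), when given, restricts the study area.  Returns a
    dict with ``rasters`` — {(year, metric, season): PhenoRaster} —,
    ``retrieval_ratio`` per year (percent of study-area pixels with at least
    one retrieved season), per-pixel ``status`` arrays, and (when ``out_dir``
    is given) the list of files written under the product naming scheme.
    """
    pcfg = preprocess_config or PreprocessConfig()
    scfg = season_config or SeasonConfig()
    t, ny, nx = stack.shape
    if len(dates) != t:
        raise ValueError("dates length must match stack time axis")
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ny, nx):
        raise ValueError("mask grid does not match the stack grid")

    years = list(years)
    out = {
        (year, metric, season): np.full((ny, nx), NODATA, dtype=np.int16)
        for year in years
        for metric in ("SOS", "EOS")
        for season in (1, 2)
    }
    status = {year: np.full((ny, nx), "masked", dtype=object) for year in years}

    for iy in range(ny):
        for ix in range(nx):
            if not mask[iy, ix]:
                continue
            series = VISeries(dates=dates, values=stack[:, iy, ix].astype(float))
            try:
                clean = preprocess(series, pcfg)
            except (InsufficientDataError, DryphenoError):
                for year in years:
                    status[year][iy, ix] = "insufficient_data"
                continue
            for year in years:
                rec = retrieve_pheno(clean, year, config=scfg)
                status[year][iy, ix] = rec.status
                for season in rec.seasons:
                    out[(year, "SOS", season.rank)][iy, ix] = int(round(season.sos))
                    out[(year, "EOS", season.rank)][iy, ix] = int(round(season.eos))

    rasters = {
        key: PhenoRaster(
            grid=grid, metric=key[1], season=key[2], year=key[0], values=arr
        )
        for key, arr in out.items()
    }
    rr = {}
    total = int(mask.sum())
    for year in years:
        retrieved = int(np.sum((status[year] == "retrieved") & mask))
        rr[year] = retrieval_ratio(retrieved, total) if total else float("nan")

    result = {"rasters": rasters, "retrieval_ratio": rr, "status": status}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for (year, metric, season), raster in rasters.items():
            path = out_dir / pheno_raster_filename(year, metric, season)
            write_pheno_raster(raster, path)
            written.append(path)
        result["files"] = sorted(written)
    return result
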