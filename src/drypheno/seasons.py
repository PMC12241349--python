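"""Growing-season detection with a dynamic pixel-wise amplitude threshold.

For a target calendar year the detector looks at a retrieval window spanning
the year plus six months on either side (Jul-01 of year−1 through Jun-30 of
year+1).  Candidate peaks are local maxima of the smoothed daily index
series; a peak qualifies as a growing season only if its index value is
greater than or equal to the *mean index over the retrieval window* — a
threshold that adapts per pixel and per year instead of a fixed amplitude
cut, which is what lets sparsely vegetated pixels with low seasonal
amplitude still be retrieved.

Per qualifying season the metrics are:

* ``left_min`` / ``right_min`` — index minima between the peak and its
  flanking troughs;
* SOS — the date the rising limb crosses
  ``left_min + f · (peak − left_min)`` (default ``f`` = 0.5);
* EOS — the date the falling limb crosses the mirrored right-side level;
* POS — the date of the peak; LOS = EOS − SOS;
* ``baseline`` = (left_min + right_min)/2 and
  ``amplitude`` = peak − baseline.

Up to two seasons are reported per year (largest amplitudes win), assigned
to the year their POS falls in; SOS/EOS are fractional day-of-year relative
to Jan-01 of the target year and may fall outside [1, 365] for seasons that
straddle the year boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import InsufficientDataError, VISeries

__all__ = [
    "SeasonConfig",
    "RetrievalWindow",
    "SeasonMetrics",
    "PhenoRecord",
    "FlatSeasonError",
    "build_retrieval_window",
    "find_candidate_peaks",
    "dynamic_threshold_filter",
    "crossing_date",
    "delineate_season",
    "retrieve_pheno",
]


class FlatSeasonError(ValueError):
    """A candidate peak has zero amplitude on one side; crossings undefined."""


@dataclass(frozen=True)
class SeasonConfig:
    """Tunables of the season detector.

    ``threshold_fraction`` is the side-amplitude fraction defining SOS/EOS
    (0.5 for satellite index series; 0.2 is conventional for GCC/GPP).
    ``min_valid_days`` is the minimum number of valid days the retrieval
    window must contain.  Peaks closer than ``min_peak_separation_days`` are
    merged, keeping the higher one.
    """

    threshold_fraction: float = 0.5
    min_peak_separation_days: int = 30
    min_valid_days: int = 180
    max_seasons: int = 2
    flat_tol: float = 1e-6
    #: minimum peak/trough prominence as a fraction of the window value range
    rel_prominence: float = 0.1


@dataclass(frozen=True)
class RetrievalWindow:
    """Target year ± six calendar months, with the mean index over valid days."""

    target_year: int
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    window_mean: float
    n_valid_days: int


@dataclass(frozen=True)
class SeasonMetrics:
    """Metrics of one retrieved growing season.

    ``sos``/``pos``/``eos`` are fractional DOY relative to Jan-01 of the
    target year (Jan-01 noon = 1.5); values ≤ 0 or > 365 indicate a season
    straddling the year boundary.
    """

    sos: float
    pos: float
    eos: float
    los: float
    peak_value: float
    left_min: float
    right_min: float
    baseline: float
    amplitude: float
    rank: int = 1

    def __post_init__(self) -> None:
        if not (self.sos < self.pos < self.eos):
            raise ValueError("season ordering violated: need sos < pos < eos")


@dataclass(frozen=True)
class PhenoRecord:
    """Retrieval outcome for one pixel/site and target year: 0–2 seasons."""

    target_year: int
    seasons: tuple[SeasonMetrics, ...]
    status: str  # retrieved | no_peak_above_mean | insufficient_data | flat_series
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seasons) > 2:
            raise ValueError("at most two seasons per year")
        pos = [s.pos for s in self.seasons]
        if pos != sorted(pos):
            raise ValueError("seasons must be sorted chronologically by pos")


# ---------------------------------------------------------------------------
# window


def window_span(target_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Retrieval-window span: Jul-01 of year−1 through Jun-30 of year+1."""
    return (
        pd.Timestamp(year=target_year - 1, month=7, day=1),
        pd.Timestamp(year=target_year + 1, month=6, day=30),
    )


def build_retrieval_window(
    series: VISeries, target_year: int, min_valid_days: int = 180
) -> RetrievalWindow:
    """Mean index over the valid days of the target year ± 6 months.

    Raises :class:`InsufficientDataError` when fewer than ``min_valid_days``
    valid days fall inside the window.
    """
    start, end = window_span(target_year)
    try:
        sub = series.slice(start, end)
    except InsufficientDataError:
        raise InsufficientDataError(
            f"series does not overlap retrieval window of {target_year}"
        ) from None
    n_valid = sub.n_valid
    if n_valid < min_valid_days:
        raise InsufficientDataError(
            f"only {n_valid} valid days in retrieval window of {target_year}, "
            f"need {min_valid_days}"
        )
    mean = float(np.mean(sub.values[sub.valid]))
    return RetrievalWindow(
        target_year=target_year,
        start_date=start,
        end_date=end,
        window_mean=mean,
        n_valid_days=n_valid,
    )


# ---------------------------------------------------------------------------
# peaks and troughs


def _window_peaks(
    series: VISeries,
    min_sep: int,
    rel_prominence: float,
    flat_tol: float,
) -> list[dict]:
    """Candidate peaks with trough bounds, per contiguous valid run.

    Peaks and troughs are located with a topographic-prominence criterion:
    a feature must rise (or dip) by at least ``rel_prominence`` of the
    window's value range to count.  This keeps residual noise wiggles on a
    season plateau from splitting one season into several, while genuine
    secondary seasons — whose dip to the inter-season trough is a large
    share of the range — survive.  Peaks closer than ``min_sep`` days are
    resolved by :func:`scipy.signal.find_peaks`' distance rule (higher peak
    wins).  Each peak's bounds are the nearest significant trough on either
    side, or the valid run's edge where no trough exists.
    """
    from scipy.signal import find_peaks as _find_peaks

    wvals = series.values[series.valid]
    if wvals.size == 0:
        return []
    prominence = max(flat_tol, rel_prominence * float(np.ptp(wvals)))
    peaks: list[dict] = []
    valid = series.valid
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        run = series.values[i:j]
        if len(run) >= 3:
            pk, _ = _find_peaks(run, prominence=prominence, distance=min_sep)
            tr, _ = _find_peaks(-run, prominence=prominence)
            for k in pk:
                left_tr = tr[tr < k]
                right_tr = tr[tr > k]
                lb = int(left_tr.max()) if left_tr.size else 0
                rb = int(right_tr.min()) if right_tr.size else len(run) - 1
                peaks.append(
                    {
                        "idx": i + int(k),
                        "value": float(run[k]),
                        "left_bound": i + lb,
                        "right_bound": i + rb,
                    }
                )
        i = j
    peaks.sort(key=lambda p: p["idx"])
    return peaks


def find_candidate_peaks(
    series: VISeries,
    window: RetrievalWindow,
    min_peak_separation_days: int = 30,
    rel_prominence: float = 0.1,
) -> list[pd.Timestamp]:
    """Dates of candidate season peaks inside the retrieval window."""
    sub = series.slice(window.start_date, window.end_date)
    peaks = _window_peaks(sub, min_peak_separation_days, rel_prominence, 1e-6)
    return [sub.dates[p["idx"]] for p in peaks]


def dynamic_threshold_filter(
    peaks: list[pd.Timestamp], series: VISeries, window: RetrievalWindow
) -> list[pd.Timestamp]:
    """Retain peaks whose index value is >= the window mean (inclusive)."""
    out = []
    for peak in peaks:
        i = series.dates.get_loc(pd.Timestamp(peak))
        if series.values[i] >= window.window_mean:
            out.append(pd.Timestamp(peak))
    return out


# ---------------------------------------------------------------------------
# crossings and delineation


def _doy(date: pd.Timestamp, target_year: int) -> float:
    """Fractional day-of-year relative to Jan-01 of ``target_year`` (Jan-01 = 1)."""
    jan1 = pd.Timestamp(year=target_year, month=1, day=1)
    return (pd.Timestamp(date) - jan1) / pd.Timedelta(days=1) + 1.0


def crossing_date(
    series: VISeries,
    level: float,
    anchor: pd.Timestamp,
    side: str,
    bound: pd.Timestamp | None = None,
) -> pd.Timestamp:
    """Threshold crossing nearest the peak, located by linear interpolation.

    ``side="left"`` returns the latest upward crossing of ``level`` at or
    before ``anchor`` (and after ``bound`` when given); ``side="right"`` the
    earliest downward crossing at or after ``anchor``.  The returned
    timestamp is fractional (sub-day resolution).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    ia = series.dates.get_loc(pd.Timestamp(anchor))
    v = series.values
    if bound is not None:
        ib = series.dates.get_loc(pd.Timestamp(bound))
    else:
        ib = 0 if side == "left" else len(v) - 1
    if side == "left":
        for i in range(ia, ib, -1):
            if v[i] >= level and v[i - 1] < level:
                frac = (level - v[i - 1]) / (v[i] - v[i - 1])
                return series.dates[i - 1] + pd.Timedelta(days=float(frac))
        if v[ib] >= level:  # level met at the bound itself
            return series.dates[ib]
    else:
        for i in range(ia, ib):
            if v[i] >= level and v[i + 1] < level:
                frac = (v[i] - level) / (v[i] - v[i + 1])
                return series.dates[i] + pd.Timedelta(days=float(frac))
        if v[ib] >= level:
            return series.dates[ib]
    raise RuntimeError(
        "no threshold crossing found; level outside the limb's range"
    )


def delineate_season(
    series: VISeries,
    peak: pd.Timestamp,
    left_bound: pd.Timestamp,
    right_bound: pd.Timestamp,
    threshold_fraction: float = 0.5,
    target_year: int | None = None,
    flat_tol: float = 1e-6,
) -> SeasonMetrics:
    """Compute season metrics for one peak between its trough bounds.

    Raises :class:`FlatSeasonError` when either side amplitude is below
    ``flat_tol`` (threshold crossings are then undefined).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    peak = pd.Timestamp(peak)
    if not (pd.Timestamp(left_bound) < peak < pd.Timestamp(right_bound)):
        raise ValueError("need left_bound < peak < right_bound")
    if target_year is None:
        target_year = int(peak.year)
    ip = series.dates.get_loc(peak)
    il = series.dates.get_loc(pd.Timestamp(left_bound))
    ir = series.dates.get_loc(pd.Timestamp(right_bound))
    peak_value = float(series.values[ip])
    left_seg = series.values[il : ip + 1][series.valid[il : ip + 1]]
    right_seg = series.values[ip : ir + 1][series.valid[ip : ir + 1]]
    left_min = float(np.min(left_seg))
    right_min = float(np.min(right_seg))
    if peak_value - left_min < flat_tol or peak_value - right_min < flat_tol:
        raise FlatSeasonError("side amplitude below tolerance; crossings undefined")
    sos_level = left_min + threshold_fraction * (peak_value - left_min)
    eos_level = right_min + threshold_fraction * (peak_value - right_min)
    sos_date = crossing_date(series, sos_level, peak, "left", bound=left_bound)
    eos_date = crossing_date(series, eos_level, peak, "right", bound=right_bound)
    baseline = 0.5 * (left_min + right_min)
    sos = _doy(sos_date, target_year)
    eos = _doy(eos_date, target_year)
    pos = _doy(peak, target_year)
    return SeasonMetrics(
        sos=sos,
        pos=pos,
        eos=eos,
        los=eos - sos,
        peak_value=peak_value,
        left_min=left_min,
        right_min=right_min,
        baseline=baseline,
        amplitude=peak_value - baseline,
    )


# ---------------------------------------------------------------------------
# orchestration


def retrieve_pheno(
    series: VISeries,
    target_year: int,
    max_seasons: int = 2,
    threshold_fraction: float = 0.5,
    config: SeasonConfig | None = None,
) -> PhenoRecord:
    """Retrieve up to ``max_seasons`` growing seasons for one target year.

    Pipeline: retrieval window → candidate peaks → dynamic window-mean
    threshold → per-peak delineation.  A season counts toward the target
    year iff its peak date falls inside that calendar year.  When more than
    ``max_seasons`` qualify, the largest amplitudes are kept and reported
    chronologically with rank 1, 2.
    """
    cfg = config or SeasonConfig()
    if threshold_fraction != cfg.threshold_fraction:
        from dataclasses import replace as _replace

        cfg = _replace(cfg, threshold_fraction=threshold_fraction)
    diagnostics: dict = {}
    try:
        window = build_retrieval_window(
            series, target_year, min_valid_days=cfg.min_valid_days
        )
    except InsufficientDataError as exc:
        return PhenoRecord(target_year, (), "insufficient_data", {"reason": str(exc)})
    diagnostics["window_mean"] = window.window_mean
    diagnostics["n_valid_days"] = window.n_valid_days

    sub = series.slice(window.start_date, window.end_date)
    wvals = sub.values[sub.valid]
    if float(np.ptp(wvals)) < cfg.flat_tol:
        return PhenoRecord(target_year, (), "flat_series", diagnostics)

    peaks = _window_peaks(
        sub, cfg.min_peak_separation_days, cfg.rel_prominence, cfg.flat_tol
    )
    diagnostics["candidate_peaks"] = [str(sub.dates[p["idx"]].date()) for p in peaks]
    if not peaks:
        return PhenoRecord(target_year, (), "no_peak_above_mean", diagnostics)

    retained = [p for p in peaks if p["value"] >= window.window_mean]
    diagnostics["n_rejected_below_mean"] = len(peaks) - len(retained)
    if not retained:
        return PhenoRecord(target_year, (), "no_peak_above_mean", diagnostics)

    seasons: list[SeasonMetrics] = []
    n_flat = 0
    for p in retained:
        peak_date = sub.dates[p["idx"]]
        if peak_date.year != target_year:
            continue
        try:
            season = delineate_season(
                sub,
                peak_date,
                sub.dates[p["left_bound"]],
                sub.dates[p["right_bound"]],
                threshold_fraction=cfg.threshold_fraction,
                target_year=target_year,
                flat_tol=cfg.flat_tol,
            )
        except FlatSeasonError:
            n_flat += 1
            continue
        seasons.append(season)
    diagnostics["n_flat_rejected"] = n_flat

    if not seasons:
        status = "flat_series" if n_flat > 0 else "no_peak_above_mean"
        return PhenoRecord(target_year, (), status, diagnostics)

    if len(seasons) > max_seasons:
        seasons = sorted(seasons, key=lambda s: -s.amplitude)[:max_seasons]
    seasons = sorted(seasons, key=lambda s: s.pos)
    seasons = [
        SeasonMetrics(
            sos=s.sos,
            pos=s.pos,
            eos=s.eos,
            los=s.los,
            peak_value=s.peak_value,
            left_min=s.left_min,
            right_min=s.right_min,
            baseline=s.baseline,
            amplitude=s.amplitude,
            rank=i + 1,
        )
        for i, s in enumerate(seasons)
    ]
    return PhenoRecord(target_year, tuple(seasons), "retrieved", diagnostics)


def records_to_table(records, site: str | None = None) -> pd.DataFrame:
    """Flatten PhenoRecords into the tabular per site-year-season schema."""
    rows = []
    for rec in records:
        if not rec.seasons:
            rows.append(
                {
                    "site": site,
                    "year": rec.target_year,
                    "season": np.nan,
                    "sos": np.nan,
                    "pos": np.nan,
                    "eos": np.nan,
                    "los": np.nan,
                    "baseline": np.nan,
                    "amplitude": np.nan,
                    "peak_value": np.nan,
                    "status": rec.status,
                }
            )
        for s in rec.seasons:
            rows.append(
                {
                    "site": site,
                    "year": rec.target_year,
                    "season": s.rank,
                    "sos": s.sos,
                    "pos": s.pos,
                    "eos": s.eos,
                    "los": s.los,
                    "baseline": s.baseline,
                    "amplitude": s.amplitude,
                    "peak_value": s.peak_value,
                    "status": rec.status,
                }
            )
    df = pd.DataFrame(rows)
    if site is None and not df.empty:
        df = df.drop(columns=["site"])
    return df
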