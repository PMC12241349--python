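"""Synthetic daily index, camera and raster series with known season truth.

Seasonal curves are double logistics — the standard parametric model for a
green-up/senescence cycle — or, optionally, a skewed rainfall-pulse shape
(rapid logistic rise, slow exponential decay) that mimics dryland response
to concentrated precipitation.  Every generator is a pure function of its
parameters and seed, and each simulated series comes with analytically
root-found true SOS/EOS dates so that retrieval error can be scored without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .series import VISeries

__all__ = [
    "SyntheticSeasonSpec",
    "TruthSeason",
    "double_logistic",
    "rainfall_pulse",
    "true_crossings",
    "simulate_series",
    "simulate_camera",
    "simulate_gpp",
    "simulate_raster",
    "SyntheticRaster",
]


@dataclass(frozen=True)
class SyntheticSeasonSpec:
    """Parameters of one synthetic growing season.

    ``b`` baseline index value, ``a`` seasonal amplitude, ``t1``/``t2``
    green-up and senescence midpoints (fractional DOY; may lie outside
    [1, 365] for boundary-straddling seasons), ``r1``/``r2`` transition
    rates (1/day).  Noise is i.i.d. Gaussian; gaps are runs of missing days
    with geometric run lengths.  Defaults describe a moderate dryland
    grass/shrub season: low winter baseline, spring green-up over a few
    weeks, slower senescence.
    """

    b: float = 0.10
    a: float = 0.25
    t1: float = 110.0
    t2: float = 260.0
    r1: float = 0.08
    r2: float = 0.06
    noise_sd: float = 0.02
    gap_fraction: float = 0.2
    gap_run_mean: float = 8.0
    seed: int = 0
    shape: str = "double_logistic"  # or "pulse"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("amplitude a must be positive")
        if self.t1 >= self.t2:
            raise ValueError("need t1 < t2")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        if self.shape not in ("double_logistic", "pulse"):
            raise ValueError("shape must be 'double_logistic' or 'pulse'")


@dataclass(frozen=True)
class TruthSeason:
    """Analytic truth for one season: fractional DOY relative to ``year``."""

    year: int
    component: int
    sos: float
    pos: float
    eos: float


def double_logistic(t, spec: SyntheticSeasonSpec):
    """b + a·(σ(r1(t−t1)) − σ(r2(t−t2))) evaluated at fractional DOY ``t``."""
    t = np.asarray(t, dtype=float)
    rise = expit(spec.r1 * (t - spec.t1))
    fall = expit(spec.r2 * (t - spec.t2))
    out = spec.b + spec.a * (rise - fall)
    return float(out) if out.ndim == 0 else out


def rainfall_pulse(t, spec: SyntheticSeasonSpec):
    """Skewed pulse: logistic rise at ``t1``, exponential decay beyond ``t2``."""
    t = np.asarray(t, dtype=float)
    rise = expit(spec.r1 * (t - spec.t1))
    decay = np.exp(-spec.r2 * np.clip(t - spec.t2, 0.0, None))
    out = spec.b + spec.a * rise * decay
    return float(out) if out.ndim == 0 else out


def _curve(spec: SyntheticSeasonSpec) -> Callable:
    return double_logistic if spec.shape == "double_logistic" else rainfall_pulse


def _pulse_only(spec: SyntheticSeasonSpec, t):
    """The zero-baseline pulse of one component (used when summing components)."""
    return _curve(spec)(t, spec) - spec.b  # type: ignore[call-arg]


def true_crossings(
    spec: SyntheticSeasonSpec,
    threshold_fraction: float = 0.5,
    span: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Analytic SOS/EOS of the noiseless curve, bisected to 1e-6 day.

    Levels are ``min + fraction · (peak − min)`` with the side minima and the
    peak taken from the noiseless curve over the evaluation span (default
    ``t1 − 4/r1 − 60`` through ``t2 + 4/r2 + 60``, wide enough for the curve
    to settle onto its baseline).  Refuses non-unimodal curves.
    """
    if span is None:
        span = (spec.t1 - 4.0 / spec.r1 - 60.0, spec.t2 + 4.0 / spec.r2 + 60.0)
    f = _curve(spec)
    grid = np.linspace(span[0], span[1], 4001)
    vals = f(grid, spec)
    ipk = int(np.argmax(vals))
    if ipk in (0, len(grid) - 1):
        raise ValueError("curve has no interior maximum over the evaluation span")
    # unimodality within tolerance: no secondary dip deeper than 1e-4 of the
    # amplitude on either limb (asymmetric double logistics have micro-dips
    # of order 1e-6·a in their slow tail, which are irrelevant to crossings)
    left, right = vals[: ipk + 1], vals[ipk:][::-1]
    dip = max(
        float(np.max(np.maximum.accumulate(left) - left)),
        float(np.max(np.maximum.accumulate(right) - right)),
    )
    if dip > 1e-4 * spec.a:
        raise ValueError("curve is not unimodal over the evaluation span")
    # refine the peak by golden-section-free bisection on the grid bracket
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda t: -f(t, spec),
        bounds=(grid[ipk - 1], grid[ipk + 1]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    t_peak = float(res.x)
    peak = float(f(t_peak, spec))
    left_min = float(np.min(vals[: ipk + 1]))
    right_min = float(np.min(vals[ipk:]))
    sos_level = left_min + threshold_fraction * (peak - left_min)
    eos_level = right_min + threshold_fraction * (peak - right_min)
    sos = brentq(lambda t: f(t, spec) - sos_level, span[0], t_peak, xtol=1e-6)
    eos = brentq(lambda t: f(t, spec) - eos_level, t_peak, span[1], xtol=1e-6)
    return float(sos), float(eos)


def _true_pos(spec: SyntheticSeasonSpec) -> float:
    """Fractional DOY of the noiseless curve maximum."""
    sos, eos = true_crossings(spec, 0.5)
    from scipy.optimize import minimize_scalar

    f = _curve(spec)
    res = minimize_scalar(
        lambda t: -f(t, spec), bounds=(sos, eos), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _nearest_trough(grid: np.ndarray, vals: np.ndarray, scale: float, side: str) -> int:
    """Index of the significant local minimum nearest the end ('left' limb)
    or start ('right' limb) of a limb grid, ignoring micro-dips."""
    from scipy.signal import find_peaks as _find_peaks

    troughs, _ = _find_peaks(-vals, prominence=0.01 * scale)
    if troughs.size == 0:
        return int(np.argmin(vals))
    return int(troughs.max() if side == "left" else troughs.min())


def _periodic_truth(
    specs: Sequence[SyntheticSeasonSpec],
    component: int,
    anchor_year: int,
    years: tuple[int, int],
    threshold_fraction: float = 0.5,
) -> tuple[float, float, float]:
    """Analytic (sos, pos, eos) of one component's season in the summed,
    annually repeated curve — the exact noiseless signal the detector sees,
    including overlapping tails of neighbouring seasons and leap-year
    calendar offsets.  DOY is relative to Jan-01 of ``anchor_year``.
    """
    from scipy.optimize import minimize_scalar

    jan1 = pd.Timestamp(year=anchor_year, month=1, day=1)
    offsets = [
        (pd.Timestamp(year=y, month=1, day=1) - jan1).days
        for y in range(years[0] - 2, years[1] + 3)
    ]

    lead = specs[0]

    def g(t):
        tt = np.asarray(t, dtype=float)
        total = np.full_like(tt, lead.b, dtype=float)
        for s in specs:
            for off in offsets:
                total = total + _pulse_only(s, tt - off)
        return total

    spec = specs[component]
    grid = np.linspace(spec.t1 - 30.0, spec.t2 + 30.0, 2001)
    vals = g(grid)
    ipk = int(np.argmax(vals))
    lo = grid[max(ipk - 1, 0)]
    hi = grid[min(ipk + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -g(np.array([t]))[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    t_peak = float(res.x)
    peak = float(g(np.array([t_peak]))[0])

    out = {}
    for side in ("left", "right"):
        if side == "left":
            limb = np.linspace(t_peak - 364.0, t_peak, 3641)
        else:
            limb = np.linspace(t_peak, t_peak + 364.0, 3641)
        lv = g(limb)
        itr = _nearest_trough(limb, lv, spec.a, side)
        side_min = float(lv[itr])
        level = side_min + threshold_fraction * (peak - side_min)
        if side == "left":
            out[side] = float(brentq(lambda t: g(np.array([t]))[0] - level,
                                     limb[itr], t_peak, xtol=1e-6))
        else:
            out[side] = float(brentq(lambda t: g(np.array([t]))[0] - level,
                                     t_peak, limb[itr], xtol=1e-6))
    return out["left"], t_peak, out["right"]


def _delete_gap_runs(
    valid: np.ndarray, gap_fraction: float, gap_run_mean: float, rng: np.random.Generator
) -> None:
    """Mark runs of days invalid (in place) until ``gap_fraction`` is reached."""
    n = len(valid)
    target = int(round(gap_fraction * n))
    guard = 0
    while int((~valid).sum()) < target and guard < 20 * n:
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / max(gap_run_mean, 1.0)))
        valid[start : start + length] = False
        guard += 1


def simulate_series(
    specs: SyntheticSeasonSpec | Sequence[SyntheticSeasonSpec],
    years: tuple[int, int] = (2009, 2011),
    seed: int | None = None,
    kind: str = "EVI2",
    with_truth: bool = True,
) -> tuple[VISeries, list[TruthSeason]]:
    """Simulate a daily index series over ``years`` (inclusive) plus truth.

    Component seasonal pulses repeat every calendar year (anchored at each
    year's Jan-01), sit on the first spec's baseline, and are summed for
    bimodal series.  Gaussian noise and geometric gap runs are controlled by
    the first spec; ``seed`` overrides the spec seed when given.

    Truth SOS/EOS are root-found on the *summed, annually repeated* noiseless
    curve — not the isolated component — so they remain exact when slow
    senescence tails of adjacent years' seasons overlap, and across leap
    years.  Pass ``with_truth=False`` to skip the (cheap but nonzero) truth
    computation.
    """
    if isinstance(specs, SyntheticSeasonSpec):
        specs = [specs]
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one season spec")
    lead = specs[0]
    rng = np.random.default_rng(lead.seed if seed is None else seed)

    start = pd.Timestamp(year=years[0], month=1, day=1)
    end = pd.Timestamp(year=years[1], month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    values = np.full(len(dates), lead.b, dtype=float)

    truths: list[TruthSeason] = []
    for ci, spec in enumerate(specs):
        for anchor_year in range(years[0] - 1, years[1] + 2):
            jan1 = pd.Timestamp(year=anchor_year, month=1, day=1)
            t_rel = (dates - jan1) / pd.Timedelta(days=1) + 1.0
            values += _pulse_only(spec, np.asarray(t_rel))
            if not with_truth:
                continue
            sos, pos, eos = _periodic_truth(specs, ci, anchor_year, years)
            pos_date = jan1 + pd.Timedelta(days=pos - 1.0)
            if start <= pos_date <= end:
                pos_year = int(pos_date.year)
                ref = pd.Timestamp(year=pos_year, month=1, day=1)
                shift = (jan1 - ref) / pd.Timedelta(days=1)
                truths.append(
                    TruthSeason(
                        year=pos_year,
                        component=ci,
                        sos=sos + shift,
                        pos=pos + shift,
                        eos=eos + shift,
                    )
                )

    if lead.noise_sd > 0:
        values = values + rng.normal(0.0, lead.noise_sd, len(values))
    valid = np.ones(len(values), dtype=bool)
    if lead.gap_fraction > 0:
        _delete_gap_runs(valid, lead.gap_fraction, lead.gap_run_mean, rng)
    values = np.where(valid, values, np.nan)
    series = VISeries(dates=dates, values=values, valid=valid, kind=kind)
    truths.sort(key=lambda tr: (tr.year, tr.pos))
    return series, truths


def simulate_camera(
    spec: SyntheticSeasonSpec,
    year: int = 2010,
    seed: int | None = None,
    obs_per_day: int = 48,
    total_dn: float = 300.0,
):
    """Simulate a 30-minute RGB camera record whose GCC follows the season.

    The seasonal curve (plus per-record noise) is inverted through fixed
    channel ratios: green carries ``gcc·total_dn`` and the remainder is split
    equally between red and blue, so per-record GCC reproduces the curve
    exactly in the noiseless case.
    """
    from .insitu import CameraSeries

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    start = pd.Timestamp(year=year, month=1, day=1)
    stamps = pd.date_range(
        start, pd.Timestamp(year=year, month=12, day=31, hour=23, minute=30),
        freq=f"{24 * 60 // obs_per_day}min",
    )
    # evaluate per calendar day so GCC is constant within a day (noiseless)
    t = (stamps.normalize() - start) / pd.Timedelta(days=1) + 1.0
    gcc = _curve(spec)(np.asarray(t), spec)
    if spec.noise_sd > 0:
        gcc = gcc + rng.normal(0.0, spec.noise_sd, len(gcc))
    gcc = np.clip(gcc, 1e-3, 1.0 - 1e-3)
    green = gcc * total_dn
    red = blue = (1.0 - gcc) * total_dn / 2.0
    return CameraSeries(
        timestamps=stamps, red_dn=red, green_dn=green, blue_dn=blue.copy()
    )


def simulate_gpp(
    spec: SyntheticSeasonSpec,
    years: tuple[int, int] = (2009, 2011),
    seed: int | None = None,
) -> tuple[VISeries, list[TruthSeason]]:
    """Daily GPP-like series: seasonal curve plus noise, clipped at zero."""
    series, truths = simulate_series(spec, years=years, seed=seed, kind="GPP")
    values = np.clip(series.values, 0.0, None)
    return series.with_values(np.where(series.valid, values, np.nan)), truths


@dataclass(frozen=True)
class SyntheticRaster:
    """Daily index stack (time, row, col) with per-pixel analytic truth.

    Bare-soil pixels are constant below the vegetation noise floor and carry
    NaN truth; ``veg_mask`` is True on vegetated pixels.
    """

    dates: pd.DatetimeIndex
    stack: np.ndarray  # (t, ny, nx)
    grid: "object"
    truth_sos: np.ndarray  # (ny, nx), DOY of target_year, NaN on bare pixels
    truth_eos: np.ndarray
    veg_mask: np.ndarray  # (ny, nx) bool
    target_year: int


def simulate_raster(
    nx: int = 20,
    ny: int = 20,
    years: tuple[int, int] = (2009, 2011),
    target_year: int = 2010,
    seed: int = 0,
    bare_fraction: float = 0.1,
    bare_value: float = 0.05,
    noise_sd: float = 0.0,
    base_spec: SyntheticSeasonSpec | None = None,
) -> SyntheticRaster:
    """Simulate a small daily raster stack with smoothly varying phenology.

    Green-up timing drifts across columns and seasonal amplitude across
    rows; exactly ``round(bare_fraction · nx · ny)`` pixels (chosen by the
    seeded RNG) are flat bare soil at ``bare_value``, below the default
    vegetation floor, so the expected retrieval ratio is known by
    construction.
    """
    from .raster import RasterGrid

    if nx * ny > 250_000:
        raise ValueError("raster too large for the synthetic generator")
    rng = np.random.default_rng(seed)
    base = base_spec or SyntheticSeasonSpec(
        noise_sd=noise_sd, gap_fraction=0.0, seed=seed
    )
    start = pd.Timestamp(year=years[0], month=1, day=1)
    end = pd.Timestamp(year=years[1], month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    nt = len(dates)
    stack = np.empty((nt, ny, nx), dtype=np.float32)
    truth_sos = np.full((ny, nx), np.nan)
    truth_eos = np.full((ny, nx), np.nan)

    n_bare = int(round(bare_fraction * nx * ny))
    flat_idx = rng.permutation(nx * ny)[:n_bare]
    veg_mask = np.ones((ny, nx), dtype=bool)
    veg_mask.ravel()[flat_idx] = False

    jan1 = pd.Timestamp(year=target_year, month=1, day=1)
    for iy in range(ny):
        for ix in range(nx):
            if not veg_mask[iy, ix]:
                col = np.full(nt, bare_value, dtype=float)
                if noise_sd > 0:
                    col = col + rng.normal(0.0, noise_sd, nt)
                stack[:, iy, ix] = col
                continue
            t1 = base.t1 + 30.0 * (ix / max(nx - 1, 1))
            amp = 0.15 + 0.20 * (iy / max(ny - 1, 1))
            spec = replace(base, t1=t1, t2=t1 + 150.0, a=amp)
            series, _ = simulate_series(
                spec, years=years, seed=int(rng.integers(0, 2**31 - 1)),
                with_truth=False,
            )
            stack[:, iy, ix] = series.values
            sos, pos, eos = _periodic_truth([spec], 0, target_year, years)
            if 1.0 <= pos <= 366.0:  # season peaks inside the target year
                truth_sos[iy, ix] = sos
                truth_eos[iy, ix] = eos

    grid = RasterGrid(x0=0.0, y0=float(ny), dx=1.0, dy=-1.0, crs="synthetic-grid")
    return SyntheticRaster(
        dates=dates,
        stack=stack,
        grid=grid,
        truth_sos=truth_sos,
        truth_eos=truth_eos,
        veg_mask=veg_mask,
        target_year=target_year,
    )
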