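# Methods

## The retrieval problem

Dryland vegetation is sparse, heterogeneous, and driven by irregular
rainfall: seasonal cycles in a satellite vegetation index are often low in
amplitude, sometimes bimodal, and frequently missed by phenology products
that require a fixed minimum seasonal amplitude. `drypheno` implements a
per-pixel retrieval that replaces the fixed amplitude cut with a *dynamic
pixel-wise threshold*: a candidate peak counts as a growing season only if
its index value is at least the mean index over a retrieval window spanning
the target year plus six calendar months on either side (Jul-01 of the
previous year through Jun-30 of the following year). Because the bar adapts
to each pixel's own signal level, low-amplitude but genuine seasons in
sparsely vegetated pixels are retained, while spurious noise peaks — which
by construction sit near the window mean — are not.

## Preprocessing chain

Input is daily NIR/Red nadir-adjusted surface reflectance with per-band QA
flags, or a precomputed daily index series. The chain is:

1. **QA screening.** A date is kept only if *both* bands carry the accepted
   flag (default `0`). Values are never altered; validity is a mask.
2. **EVI2.** `EVI2 = 2.5 (NIR − Red) / (NIR + 2.4 Red + 1)` — a two-band
   index that suppresses soil-background and atmospheric effects without
   needing a blue band.
3. **Noise floor.** Index values ≤ 0.08 (inclusive) are masked as
   non-vegetated or contaminated (bare soil, cloud shadow, snow). Masking
   happens *before* gap filling so the spline never leans on contaminated
   samples.
4. **Gap filling.** Interior gaps of at most `max_gap_days` (default 60)
   are bridged by a cubic univariate spline fitted to the valid points.
   The smoothing parameter is `s = n·σ̂²` with `σ̂` a robust noise estimate
   (1.4826 · median |Δ| / √2 over day-adjacent first differences): for
   noiseless data this reduces to exact interpolation, while for noisy data
   it avoids the large oscillations an exact cubic interpolant develops
   inside gaps (we measured overshoots exceeding the seasonal amplitude).
   Only gap values are replaced; valid samples are returned bit-identical.
   Gaps longer than `max_gap_days` stay invalid — a pixel-year with a
   missing season is reported unretrievable rather than invented.
5. **Savitzky–Golay smoothing** on each contiguous valid run, default
   window 31 days and polynomial order 2. The window/order are not fixed by
   the method definition; 31/2 preserves seasonal curvature of daily series
   while suppressing day-to-day noise, and both are exposed in
   `PreprocessConfig`. Runs shorter than the window are left unsmoothed.

## Season detection

For each target year:

- **Window.** Mean index over valid days of the 24-month retrieval window;
  at least `min_valid_days` (default 180) valid days are required, else the
  year is `insufficient_data`.
- **Peaks and troughs.** Local maxima/minima of the smoothed series found
  with a topographic-prominence criterion (`scipy.signal.find_peaks`,
  default prominence 10% of the window's value range, minimum peak
  separation 30 days). Prominence is essential at daily resolution:
  residual noise on a broad season plateau otherwise splits one season into
  several. A genuine secondary season dips much deeper between peaks than
  noise wiggles do, so it survives the criterion.
- **Dynamic threshold.** Peaks with smoothed value ≥ window mean are
  retained; the comparison is inclusive.
- **Delineation.** For each retained peak, the side minima are taken
  between the peak and its nearest significant trough (or the valid run
  edge). SOS is the last upward crossing of
  `left_min + f·(peak − left_min)` before the peak, EOS the first downward
  crossing of the mirrored right-side level after it, both located by
  linear interpolation between daily samples; `f` defaults to 0.5 for
  satellite index series. POS is the peak date, LOS = EOS − SOS, baseline =
  (left_min + right_min)/2, amplitude = peak − baseline. Taking the
  crossing *closest to the peak* keeps SOS/EOS inside the season core when
  noisy shoulders cross the level repeatedly.
- **Year assignment and capping.** A season belongs to the year its POS
  falls in; SOS/EOS are fractional day-of-year relative to that year's
  Jan-01 and may be ≤ 0 or > 365 for boundary-straddling seasons. At most
  two seasons are reported per year; if more qualify, the two largest
  amplitudes are kept and reported chronologically (rank 1, 2).
- **Statuses.** `retrieved`; `insufficient_data` (window coverage too low,
  including fully sub-floor pixels); `flat_series` (window range below
  tolerance, or every candidate rejected for zero side amplitude);
  `no_peak_above_mean` (candidates exist but none qualifies in the target
  year).

By construction every retrieved season satisfies SOS < POS < EOS and
LOS = EOS − SOS — orderings that some global products violate.

## In-situ phenology

Camera series are 30-minute mean RGB digital numbers per region of
interest. The green chromatic coordinate `GCC = G/(R+G+B)` is composited to
a daily series as the day's **90th percentile** (linear-interpolation
percentile convention, pinned for reproducibility), requiring at least
`min_obs_per_day` (default 6) observations per day. Flux-tower GPP is
consumed as daily values with negative values (partitioning artifacts)
masked. Both are smoothed with the same SG filter and passed to the same
season detector with `f = 0.2`: the 20% side-amplitude level tracks the
subtler seasonal dynamics of continuous GCC/GPP records. The side-minima
baseline definition is reused unchanged for consistency with the satellite
retrieval.

## Validation statistics

- Retrieval ratio `RR = m/M × 100` over the study-area mask.
- Taylor statistics for matched product/observation pairs: Pearson r,
  centred RMSE and the two standard deviations, all with population
  (divide-by-n) normalisation so that
  `cRMSE² = SD_F² + SD_O² − 2·SD_F·SD_O·r` holds exactly. (The centred RMSE
  is the root mean square of `(F_i − F̄) − (O_i − Ō)`; a published variant
  that squares the *product* of anomalies is dimensionally inconsistent and
  breaks this identity, so the standard form is used.)
- Yearly summaries: mean absolute error per year, then mean ± population SD
  across years.
- Amplitude stratification: absolute errors split into amplitude quantile
  groups (terciles by default) plus the least-squares slope of error on
  amplitude, to expose the retrieval's sensitivity to signal strength.

## Synthetic data and what it does (not) show

The generator produces daily series as annually repeated seasonal pulses on
a constant baseline — a double logistic
`b + a·(σ(r1(t−t1)) − σ(r2(t−t2)))`, or optionally a skewed rainfall-pulse
shape (fast logistic rise, slow exponential decay) — plus i.i.d. Gaussian
noise and missing-day runs with geometric lengths. Defaults describe a
moderate dryland season: baseline 0.10, amplitude 0.25, green-up midpoint
DOY 110, senescence midpoint DOY 260, rates 0.08/0.06 d⁻¹, noise SD 0.02,
20% of days missing in runs of mean length 8. Camera series invert the GCC
curve through fixed channel ratios (GCC constant within a day), GPP series
are clipped at zero, and raster stacks vary green-up timing across columns
and amplitude across rows with an exactly known fraction of flat bare-soil
pixels — so the expected retrieval ratio is known by construction.

Truth SOS/EOS are root-found (bisection to 1e−6 day) on the *summed,
annually repeated* noiseless curve, not the isolated pulse: with slow
senescence rates the tails of adjacent years' seasons overlap and shift the
inter-season trough, and the calendar (including leap years) offsets each
repetition. The single-season closed-form oracle (`true_crossings`) is kept
for isolated-curve checks and refuses curves whose secondary dip exceeds
1e−4 of the amplitude (asymmetric double logistics have genuine micro-dips
of order 1e−6·a in their slow tail).

What the synthetic tests do **not** show: performance under real
autocorrelated noise (cloud regimes, soil moisture darkening), mixed-pixel
heterogeneity, interannual timing variability, or disturbance. Recovery
numbers on synthetic data are upper bounds on real-data accuracy. Synthetic
baselines in recovery sweeps sit above the 0.08 floor; a sub-floor baseline
censors the dormant season by design, which is exercised separately as a
status test, not scored as recovery error.

## Raster products

Per-pixel results are exported one GeoTIFF per (year, metric, season) named
`GDPD_<year>_<SOS|EOS>_<season1|season2>.tif`, DOY as signed 16-bit
integers rounded to the nearest day, nodata −32768 exactly on pixels that
are masked or not `retrieved` (tabular output keeps fractional dates; DOY
outside [1, 365] encodes boundary-straddling seasons). Georeferencing uses
standard GeoTIFF tags (pixel scale, tiepoint, GDAL nodata) via `tifffile`,
with the CRS carried as a string; only axis-aligned north-up grids are
supported and reprojection is out of scope. Masks: aridity index < 0.65
(strict) selects drylands; land-cover masks exclude listed classes in every
supplied year and optionally require class stability across years. The
resolution-degradation utilities composite a daily series into n-day bins
(mean or max, bin midpoint timestamp, linear re-interpolation to daily so
the same detector applies) and block-average stacks spatially, ignoring
missing pixels.

## Problem sizes and numerical choices

Test and acceptance runs use 3-year daily series (~1100 samples), sweeps of
50–500 random season specifications, and 50×50×2-year raster stacks; these
sizes give stable medians while keeping the whole suite fast on a single
core. Tie-breaks and tolerances: flat-season tolerance 1e−6 index units;
peak prominence 10% of window range; crossing equality at a sample resolves
to that sample; season capping prefers larger amplitude, then chronological
order; percentile convention linear interpolation. All tunables live in
`PreprocessConfig` and `SeasonConfig` and can be set from a TOML/YAML
config file.

## Known limitations

- The dynamic threshold can still miss very low-amplitude events (e.g.
  post-disturbance recovery) whose peaks stay below the window mean.
- SG window/order and the gap-fill noise adaptation are heuristics for
  daily series; 8- or 16-day inputs should be re-interpolated to daily (the
  temporal aggregation utility does this) and may warrant a shorter window.
- GCC/GPP season extraction reuses the satellite baseline definition
  (side minima); other conventions (global minimum per year) would shift
  SOS/EOS by a few days on asymmetric seasons.
- No reprojection, mosaicking, or sensor transfer; inputs are assumed
  co-registered.
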