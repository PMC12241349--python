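"""Evaluation statistics: retrieval ratio, Taylor statistics, error summaries.

The retrieval ratio RR = m/M × 100 measures spatial coverage: the share of
study-area pixels for which phenology was successfully retrieved.  Agreement
between product estimates F and in-situ observations O is summarised with
Taylor-diagram statistics — Pearson correlation r, centred RMSE and the two
standard deviations — which obey the law-of-cosines identity

    cRMSE² = SD_F² + SD_O² − 2·SD_F·SD_O·r.

All SDs use the population (divide-by-n) convention so the identity holds
exactly.  Error summaries group matched site-year pairs by year and report
the mean absolute error per year and its mean ± population SD across years;
amplitude stratification splits pairs into quantile groups by seasonal
amplitude to expose the retrieval's sensitivity to signal strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MatchedPairs",
    "TaylorStats",
    "retrieval_ratio",
    "taylor_stats",
    "match_site_years",
    "yearly_error_summary",
    "stratify_errors_by_amplitude",
    "taylor_diagram",
]


@dataclass(frozen=True)
class MatchedPairs:
    """Matched product/observation values per site-year.

    ``f`` are product estimates and ``o`` observations (fractional DOY);
    ``amplitude`` optionally carries the product pixel's seasonal amplitude.
    """

    site: np.ndarray
    year: np.ndarray
    f: np.ndarray
    o: np.ndarray
    amplitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        site = np.asarray(self.site)
        year = np.asarray(self.year)
        f = np.asarray(self.f, dtype=float)
        o = np.asarray(self.o, dtype=float)
        n = len(f)
        if not (len(site) == len(year) == len(o) == n):
            raise ValueError("all pair columns must have equal length")
        if n and (np.isnan(f).any() or np.isnan(o).any()):
            raise ValueError("matched pairs must not contain missing values")
        object.__setattr__(self, "site", site)
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "o", o)
        if self.amplitude is not None:
            amp = np.asarray(self.amplitude, dtype=float)
            if len(amp) != n:
                raise ValueError("amplitude must match pair length")
            object.__setattr__(self, "amplitude", amp)

    def __len__(self) -> int:
        return len(self.f)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"site": self.site, "year": self.year, "f": self.f, "o": self.o}
        )
        if self.amplitude is not None:
            df["amplitude"] = self.amplitude
        return df


@dataclass(frozen=True)
class TaylorStats:
    """r, centred RMSE and population SDs for one matched set (units: days)."""

    r: float
    crmse: float
    sd_f: float
    sd_o: float
    n: int

    def cosine_residual(self) -> float:
        """cRMSE² − (SD_F² + SD_O² − 2·SD_F·SD_O·r); ~0 up to rounding."""
        return self.crmse**2 - (
            self.sd_f**2 + self.sd_o**2 - 2.0 * self.sd_f * self.sd_o * self.r
        )


def retrieval_ratio(m: int, M: int) -> float:
    """Percentage of pixels with retrieved phenology: m/M × 100."""
    if M <= 0:
        raise ValueError("total pixel count M must be positive")
    if not 0 <= m <= M:
        raise ValueError("need 0 <= m <= M")
    return 100.0 * m / M


def taylor_stats(pairs: MatchedPairs) -> TaylorStats:
    """Correlation, centred RMSE and population SDs of a matched set.

    With fewer than two pairs or zero variance on either side the
    correlation is NaN (with a warning); cRMSE and the SDs are still
    returned.
    """
    f, o = pairs.f, pairs.o
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least two matched pairs")
    fa = f - f.mean()
    oa = o - o.mean()
    sd_f = float(np.sqrt(np.mean(fa**2)))
    sd_o = float(np.sqrt(np.mean(oa**2)))
    crmse = float(np.sqrt(np.mean((fa - oa) ** 2)))
    if sd_f == 0.0 or sd_o == 0.0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        r = float("nan")
    else:
        r = float(np.mean(fa * oa) / (sd_f * sd_o))
    return TaylorStats(r=r, crmse=crmse, sd_f=sd_f, sd_o=sd_o, n=n)


def match_site_years(
    product: pd.DataFrame,
    obs: pd.DataFrame,
    metric: str = "sos",
    season: int = 1,
) -> MatchedPairs:
    """Inner-join product and observation tables on (site, year).

    Both tables use the tabular retrieval schema (columns ``site``, ``year``,
    ``season``, ``sos``, ``eos``, ... and optionally ``amplitude``).  Pairs
    keep only site-years where *both* sides retrieved the requested metric
    for the requested season, ordered by site then year.
    """
    metric = metric.lower()
    if metric not in ("sos", "pos", "eos", "los"):
        raise ValueError("metric must be one of sos, pos, eos, los")

    def _side(df: pd.DataFrame, value_name: str, keep_amp: bool) -> pd.DataFrame:
        cols = ["site", "year", metric] + (
            ["amplitude"] if keep_amp and "amplitude" in df.columns else []
        )
        out = df.loc[df["season"] == season, cols].dropna(subset=[metric])
        return out.rename(columns={metric: value_name})

    left = _side(product, "f", keep_amp=True)
    right = _side(obs, "o", keep_amp=False)
    merged = left.merge(right, on=["site", "year"], how="inner")
    merged = merged.sort_values(["site", "year"]).reset_index(drop=True)
    amp = merged["amplitude"].to_numpy() if "amplitude" in merged.columns else None
    return MatchedPairs(
        site=merged["site"].to_numpy(),
        year=merged["year"].to_numpy(),
        f=merged["f"].to_numpy(),
        o=merged["o"].to_numpy(),
        amplitude=amp,
    )


def yearly_error_summary(pairs: MatchedPairs) -> dict:
    """Mean absolute error per year, and mean ± population SD across years."""
    if len(pairs) == 0:
        raise ValueError("no matched pairs")
    df = pairs.to_frame()
    df["abs_err"] = np.abs(df["f"] - df["o"])
    per_year = df.groupby("year")["abs_err"].mean()
    yearly = per_year.to_numpy()
    return {
        "per_year": per_year.to_dict(),
        "mean": float(np.mean(yearly)),
        "sd": float(np.sqrt(np.mean((yearly - np.mean(yearly)) ** 2))),
    }


def stratify_errors_by_amplitude(pairs: MatchedPairs, n_groups: int = 3) -> pd.DataFrame:
    """Quantile-stratify absolute errors by seasonal amplitude.

    Splits pairs into ``n_groups`` amplitude quantile groups (terciles by
    default) and reports per group the pair count, mean and population SD of
    |F−O|, plus (as a frame attribute ``slope``) the least-squares slope of
    error on amplitude.  With fewer distinct amplitudes than groups the
    split degrades to fewer groups with a warning.
    """
    if pairs.amplitude is None:
        raise ValueError("pairs carry no amplitude column")
    err = np.abs(pairs.f - pairs.o)
    amp = pairs.amplitude
    k = min(n_groups, len(np.unique(amp)), len(err))
    if k < n_groups:
        warnings.warn(
            f"only {k} amplitude group(s) possible, requested {n_groups}",
            stacklevel=2,
        )
    if k <= 1:
        labels = pd.Series(np.zeros(len(err), dtype=int))
    else:
        labels = pd.qcut(amp, q=k, labels=False, duplicates="drop")
    df = pd.DataFrame({"group": labels, "amplitude": amp, "abs_err": err})
    out = (
        df.groupby("group")
        .agg(
            n=("abs_err", "size"),
            amplitude_mid=("amplitude", "median"),
            mean_err=("abs_err", "mean"),
            sd_err=("abs_err", lambda x: float(np.sqrt(np.mean((x - x.mean()) ** 2)))),
        )
        .reset_index()
    )
    if np.ptp(amp) > 0:
        slope = float(np.polyfit(amp, err, 1)[0])
    else:
        slope = 0.0
    out.attrs["slope"] = slope
    return out


def taylor_diagram(stats: dict[str, TaylorStats], reference: str, path=None):
    """Taylor diagram on polar axes: radius = SD, angle = arccos(r).

    ``stats`` maps label → TaylorStats; ``reference`` names the entry whose
    SD_O defines the observation point.  Returns the matplotlib figure and
    writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(90)
    sd_o = stats[reference].sd_o
    ax.plot([0.0], [sd_o], "ro", label="observations")
    for label, st in stats.items():
        if np.isnan(st.r):
            continue
        theta = float(np.arccos(np.clip(st.r, -1.0, 1.0)))
        ax.plot([theta], [st.sd_f], "*", markersize=10, label=label)
    ax.set_xlabel("standard deviation (days)")
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig
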