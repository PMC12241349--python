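"""Core time-series containers for phenology retrieval.

Two containers cover everything the pipeline moves around:

* :class:`ReflectanceSeries` — raw per-date NIR/Red surface reflectance with
  per-band quality-assurance flags, as delivered by daily NBAR products.
* :class:`VISeries` — a *contiguous daily* vegetation-index series with an
  explicit validity mask.  The same container carries EVI2, camera GCC
  composites and flux-tower GPP, so the season detector is agnostic to the
  index being analysed.

Invalid observations are always carried in the boolean ``valid`` mask, never
as sentinel numbers; values at invalid positions are NaN by convention but
are never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DryphenoError",
    "EmptyInputError",
    "InsufficientDataError",
    "ReflectanceSeries",
    "VISeries",
]


class DryphenoError(Exception):
    """Base class for errors raised by this package."""


class EmptyInputError(DryphenoError, ValueError):
    """An operation received an empty series."""


class InsufficientDataError(DryphenoError, ValueError):
    """Too few valid observations to perform the requested operation."""


def _as_datetime_index(dates: Iterable) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(dates)
    if idx.tz is not None:
        idx = idx.tz_localize(None)
    return idx


@dataclass(frozen=True)
class ReflectanceSeries:
    """Dated NIR/Red reflectance with per-band QA flags for one pixel or site.

    Dates must be strictly increasing but need not be contiguous; missing
    days are simply absent.  ``valid`` marks records that survived quality
    screening (all true on construction unless given).
    """

    dates: pd.DatetimeIndex
    nir: np.ndarray
    red: np.ndarray
    qa_nir: np.ndarray
    qa_red: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dates = _as_datetime_index(self.dates)
        object.__setattr__(self, "dates", dates)
        n = len(dates)
        if n == 0:
            raise EmptyInputError("reflectance series is empty")
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        for name in ("nir", "red"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        for name in ("qa_nir", "qa_red"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        if self.valid is None:
            valid = np.ones(n, dtype=bool)
        else:
            valid = np.asarray(self.valid, dtype=bool).copy()
            if valid.shape != (n,):
                raise ValueError("valid mask has wrong length")
        # reflectance outside [0, 1] cannot be trusted
        with np.errstate(invalid="ignore"):
            physical = (
                np.isfinite(self.nir)
                & np.isfinite(self.red)
                & (self.nir >= 0.0)
                & (self.nir <= 1.0)
                & (self.red >= 0.0)
                & (self.red <= 1.0)
            )
        valid &= physical
        object.__setattr__(self, "valid", valid)

    def __len__(self) -> int:
        return len(self.dates)

    def with_valid(self, valid: np.ndarray) -> "ReflectanceSeries":
        return replace(self, valid=np.asarray(valid, dtype=bool))


@dataclass(frozen=True)
class VISeries:
    """Daily vegetation-index series on a contiguous calendar grid.

    ``kind`` labels what the values are (``"EVI2"``, ``"GCC"`` or ``"GPP"``);
    the season detector treats them identically.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind: str = "EVI2"

    def __post_init__(self) -> None:
        dates = _as_datetime_index(self.dates)
        n = len(dates)
        if n == 0:
            raise EmptyInputError("index series is empty")
        deltas = np.diff(dates.asi8)
        if n > 1 and not np.all(deltas == deltas[0]) or (
            n > 1 and dates[1] - dates[0] != pd.Timedelta(days=1)
        ):
            raise ValueError("dates must be contiguous daily with no duplicates")
        object.__setattr__(self, "dates", dates)
        values = np.asarray(self.values, dtype=float).copy()
        if values.shape != (n,):
            raise ValueError(f"values must have length {n}")
        if self.valid is None:
            valid = np.isfinite(values)
        else:
            valid = np.asarray(self.valid, dtype=bool).copy()
            if valid.shape != (n,):
                raise ValueError("valid mask has wrong length")
            valid &= np.isfinite(values)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_observations(
        cls, dates: Iterable, values: Iterable, kind: str = "EVI2"
    ) -> "VISeries":
        """Build a contiguous daily series from possibly gappy observations.

        Days absent from ``dates`` become invalid (NaN) placeholders.
        """
        obs = pd.Series(
            np.asarray(list(values), dtype=float), index=_as_datetime_index(dates)
        )
        if obs.empty:
            raise EmptyInputError("no observations supplied")
        obs = obs[~obs.index.duplicated(keep="first")].sort_index()
        full = pd.date_range(obs.index[0].normalize(), obs.index[-1].normalize(), freq="D")
        filled = obs.reindex(full)
        return cls(dates=full, values=filled.to_numpy(), kind=kind)

    # -- helpers ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def with_values(self, values: np.ndarray, valid: np.ndarray | None = None) -> "VISeries":
        return VISeries(
            dates=self.dates,
            values=values,
            valid=self.valid if valid is None else valid,
            kind=self.kind,
        )

    def slice(self, start: pd.Timestamp, end: pd.Timestamp) -> "VISeries":
        """Sub-series covering ``[start, end]`` (inclusive, clipped to span)."""
        mask = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not mask.any():
            raise InsufficientDataError("series does not overlap requested span")
        return VISeries(
            dates=self.dates[mask],
            values=self.values[mask],
            valid=self.valid[mask],
            kind=self.kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "value": self.values, "valid": self.valid}
        )
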