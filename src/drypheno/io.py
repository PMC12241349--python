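"""CSV readers for site series and config-file loading (TOML or YAML)."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import pandas as pd

from .insitu import CameraSeries
from .preprocess import PreprocessConfig
from .seasons import SeasonConfig
from .series import ReflectanceSeries, VISeries

__all__ = [
    "read_reflectance_csv",
    "read_vi_csv",
    "read_camera_csv",
    "read_gpp_csv",
    "load_config",
]


def read_reflectance_csv(path) -> ReflectanceSeries:
    """Site CSV with columns date, nir, red, qa_nir, qa_red."""
    df = pd.read_csv(path, parse_dates=["date"])
    return ReflectanceSeries(
        dates=pd.DatetimeIndex(df["date"]),
        nir=df["nir"].to_numpy(float),
        red=df["red"].to_numpy(float),
        qa_nir=df["qa_nir"].to_numpy(),
        qa_red=df["qa_red"].to_numpy(),
    )


def read_vi_csv(path, kind: str = "EVI2") -> VISeries:
    """Precomputed index CSV with columns date, value."""
    df = pd.read_csv(path, parse_dates=["date"])
    return VISeries.from_observations(df["date"], df["value"], kind=kind)


def read_camera_csv(path) -> CameraSeries:
    """Camera CSV with columns timestamp, red_dn, green_dn, blue_dn."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return CameraSeries(
        timestamps=pd.DatetimeIndex(df["timestamp"]),
        red_dn=df["red_dn"].to_numpy(float),
        green_dn=df["green_dn"].to_numpy(float),
        blue_dn=df["blue_dn"].to_numpy(float),
    )


def read_gpp_csv(path) -> VISeries:
    """Flux CSV with columns date, gpp; negative GPP is masked."""
    from .insitu import prepare_gpp

    df = pd.read_csv(path, parse_dates=["date"])
    return prepare_gpp(df["date"], df["gpp"].to_numpy(float))


def _filter_kwargs(cls, mapping: dict) -> dict:
    names = {f.name for f in fields(cls)}
    return {k: v for k, v in mapping.items() if k in names}


def load_config(path) -> tuple[PreprocessConfig, SeasonConfig]:
    """Load preprocessing and season tunables from a TOML or YAML file.

    Recognised sections are ``[preprocess]`` and ``[seasons]``; unknown keys
    are ignored so config files may carry extra metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    pre = PreprocessConfig(**_filter_kwargs(PreprocessConfig, data.get("preprocess", {})))
    sea = SeasonConfig(**_filter_kwargs(SeasonConfig, data.get("seasons", {})))
    return pre, sea


def write_pairs_csv(pairs, path) -> None:
    """Write matched pairs as CSV (site, year, f, o[, amplitude])."""
    pairs.to_frame().to_csv(path, index=False)


def read_pairs_csv(path):
    """Read a matched-pairs CSV written by :func:`write_pairs_csv`."""
    from .validate import MatchedPairs

    df = pd.read_csv(path)
    amp = df["amplitude"].to_numpy(float) if "amplitude" in df.columns else None
    return MatchedPairs(
        site=df["site"].to_numpy(),
        year=df["year"].to_numpy(),
        f=df["f"].to_numpy(float),
        o=df["o"].to_numpy(float),
        amplitude=amp,
    )
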