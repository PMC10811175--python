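"""Seasonal agroclimatic indices from daily weather series.

These are the covariates used to partition tricot rankings: the longest dry
spell (consecutive days with precipitation < 1 mm), the longest wet spell
(precipitation > 1 mm), the longest hot spell (tmax > 35 degC) and the mean
diurnal temperature range (tmax - tmin) over a crop season.  Thresholds are
strict inequalities; a day with precipitation exactly 1 mm belongs to
neither a dry nor a wet spell.  Missing days break spell runs.

A weather series is a DataFrame with columns ``date`` (ISO-8601 or
datetime), ``tmax``, ``tmin``, ``precip`` (degC, degC, mm/day).  The season
window is half-open: [start, start + length days).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "SeasonWindow",
    "AgroIndices",
    "load_weather",
    "max_spell",
    "mean_dtr",
    "compute_indices",
]

DRY_THRESHOLD_MM = 1.0
WET_THRESHOLD_MM = 1.0
HOT_THRESHOLD_C = 35.0


@dataclass(frozen=True)
class SeasonWindow:
    """Crop season: planting date plus length in days, [start, start+length)."""

    start: pd.Timestamp
    length: int

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        if self.length < 1:
            raise ValidationError("season length must be >= 1 day")

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=self.length)


@dataclass(frozen=True)
class AgroIndices:
    max_dry_spell: int
    max_wet_spell: int
    max_hot_spell: int
    mean_dtr: float

    def to_dict(self) -> dict:
        return {
            "max_dry_spell": self.max_dry_spell,
            "max_wet_spell": self.max_wet_spell,
            "max_hot_spell": self.max_hot_spell,
            "mean_dtr": round(self.mean_dtr, 4),
        }


def load_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    for col in ("date", "tmax", "tmin", "precip"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    return validate_weather(df)


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    if not df["date"].is_monotonic_increasing or df["date"].duplicated().any():
        raise ValidationError("dates must be strictly increasing")
    both = df["tmax"].notna() & df["tmin"].notna()
    if (df.loc[both, "tmax"] < df.loc[both, "tmin"]).any():
        raise ValidationError("tmax < tmin on some day")
    if (df["precip"].dropna() < 0).any():
        raise ValidationError("negative precipitation")
    return df


def _window_slice(series: pd.DataFrame, window: SeasonWindow) -> pd.DataFrame:
    df = validate_weather(series)
    if window.start < df["date"].iloc[0] or window.end - pd.Timedelta(days=1) > df["date"].iloc[-1]:
        raise ValidationError("season window extends beyond the weather series")
    sel = (df["date"] >= window.start) & (df["date"] < window.end)
    out = df.loc[sel]
    if out.empty:
        raise ValidationError("empty season window")
    return out


def _longest_run(flags: np.ndarray) -> int:
    """Longest run of True; NaN-derived False entries break runs."""
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def max_spell(series: pd.DataFrame, window: SeasonWindow, condition: str,
              threshold: float | None = None) -> int:
    """Longest run of consecutive in-window days satisfying a condition.

    condition: 'dry' (precip < threshold, default 1 mm), 'wet'
    (precip > threshold, default 1 mm) or 'hot' (tmax > threshold,
    default 35 degC).  Missing observations break runs.
    """
    df = _window_slice(series, window)
    if condition == "dry":
        thr = DRY_THRESHOLD_MM if threshold is None else threshold
        col = df["precip"]
        flags = (col < thr) & col.notna()
    elif condition == "wet":
        thr = WET_THRESHOLD_MM if threshold is None else threshold
        col = df["precip"]
        flags = (col > thr) & col.notna()
    elif condition == "hot":
        thr = HOT_THRESHOLD_C if threshold is None else threshold
        col = df["tmax"]
        flags = (col > thr) & col.notna()
    else:
        raise ValidationError(f"unknown spell condition {condition!r}")
    if col.isna().all():
        warnings.warn(f"all {condition}-spell inputs missing in window; spell = 0",
                      stacklevel=2)
        return 0
    return _longest_run(flags.to_numpy())


def mean_dtr(series: pd.DataFrame, window: SeasonWindow) -> float:
    """Mean diurnal temperature range (tmax - tmin) over in-window days
    where both temperatures are present."""
    df = _window_slice(series, window)
    both = df["tmax"].notna() & df["tmin"].notna()
    if not both.any():
        raise ValidationError("no day in window has both tmax and tmin")
    return float((df.loc[both, "tmax"] - df.loc[both, "tmin"]).mean())


def compute_indices(series: pd.DataFrame, window: SeasonWindow) -> AgroIndices:
    """All four seasonal indices for one location."""
    return AgroIndices(
        max_dry_spell=max_spell(series, window, "dry"),
        max_wet_spell=max_spell(series, window, "wet"),
        max_hot_spell=max_spell(series, window, "hot"),
        mean_dtr=mean_dtr(series, window),
    )
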