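"""Growing degree days and seasonal climate covariates.

Growing degree days (GDD) are the phenological clock of the emergence
model: daily heat accumulation above a base temperature (default 10 °C)
summed from a start date (default 1 April, the start of the Austrian maize
growing season).  The seasonal covariates entering the regressions on the
Gompertz parameters are the mean winter temperature (1 Jan-31 Mar), the
mean spring temperature (1 Apr-30 Jun) and the winter precipitation sum,
each computed from the daily weather series of the station nearest a trap.

Weather series are plain pandas DataFrames with columns
``station_id, date, tmin, tmax, precip`` (ISO dates, °C, mm/day).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "DIALECT_AVERAGE",
    "DIALECT_AS_PRINTED",
    "SeasonCovariates",
    "daily_gdd",
    "cumulative_gdd",
    "season_covariates",
    "weekly_z",
    "nearest_station",
    "validate_weather",
]

#: conventional degree-day formula, max((Tmax+Tmin)/2 - Tbase, 0)
DIALECT_AVERAGE = "average"
#: half-range variant max((Tmax-Tmin)/2 - Tbase, 0), kept for fidelity experiments
DIALECT_AS_PRINTED = "as_printed"

DEFAULT_TBASE = 10.0
DEFAULT_START = (4, 1)  # 1 April


@dataclass(frozen=True)
class SeasonCovariates:
    """Per trap-year climate and land-use covariates."""

    trap_id: object
    year: int
    winter_temp: float  # mean daily-mean °C, 1 Jan-31 Mar
    spring_temp: float  # mean daily-mean °C, 1 Apr-30 Jun
    winter_precip: float  # mm summed 1 Jan-31 Mar
    maize: float  # % of municipal agricultural area in maize
    year_index: int  # years since first study year

    def __post_init__(self) -> None:
        if self.winter_precip < 0:
            raise ValueError("winter_precip must be non-negative")
        if self.year_index < 0:
            raise ValueError("year_index must be non-negative")


def validate_weather(series: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a single-station daily weather table."""
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in weather series")
    df = df.sort_values("date").reset_index(drop=True)
    if (df["tmin"] > df["tmax"]).any():
        raise ValueError("tmin > tmax in weather series")
    if (df["precip"] < 0).any():
        raise ValueError("negative precipitation in weather series")
    return df


def daily_gdd(tmax, tmin, tbase: float = DEFAULT_TBASE, dialect: str = DIALECT_AVERAGE):
    """Degree days for one day: heat of the daily mean above ``tbase``, floored at 0."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    if dialect == DIALECT_AVERAGE:
        core = (tmax + tmin) / 2.0 - tbase
    elif dialect == DIALECT_AS_PRINTED:
        core = (tmax - tmin) / 2.0 - tbase
    else:
        raise ValueError(f"unknown GDD dialect {dialect!r}")
    return np.maximum(core, 0.0)


def cumulative_gdd(
    series: pd.DataFrame,
    start_date: date | str | None = None,
    tbase: float = DEFAULT_TBASE,
    dialect: str = DIALECT_AVERAGE,
) -> pd.DataFrame:
    """Running degree-day sum from ``start_date`` (default 1 April of the series year).

    Returns a DataFrame with columns ``date, daily_gdd, cumulative_gdd``;
    the cumulative column is non-decreasing by construction.  Gaps in daily
    coverage after the start date are rejected.
    """
    df = validate_weather(series)
    if start_date is None:
        year = int(df["date"].dt.year.iloc[0])
        start_date = date(year, *DEFAULT_START)
    start = pd.Timestamp(start_date)
    df = df[df["date"] >= start].reset_index(drop=True)
    if df.empty or df["date"].iloc[0] != start:
        raise ValueError(f"weather series does not cover start date {start.date()}")
    gaps = df["date"].diff().dropna()
    if (gaps != pd.Timedelta(days=1)).any():
        raise ValueError("gap in daily weather coverage after start date")
    daily = daily_gdd(df["tmax"].to_numpy(), df["tmin"].to_numpy(), tbase, dialect)
    return pd.DataFrame(
        {"date": df["date"], "daily_gdd": daily, "cumulative_gdd": np.cumsum(daily)}
    )


def _window_mask(dates: pd.Series, year: int, lo: tuple[int, int], hi: tuple[int, int]):
    return (dates >= pd.Timestamp(date(year, *lo))) & (dates <= pd.Timestamp(date(year, *hi)))


def season_covariates(
    series: pd.DataFrame,
    year: int,
    trap_id,
    maize: float,
    first_year: int,
) -> SeasonCovariates:
    """Seasonal covariates for one trap-year from its station's daily weather.

    Winter = 1 Jan-31 Mar, spring = 1 Apr-30 Jun, both inclusive; daily mean
    temperature is (tmin+tmax)/2.  Incomplete windows are rejected.
    """
    df = validate_weather(series)
    df = df[df["date"].dt.year == year]
    winter = df[_window_mask(df["date"], year, (1, 1), (3, 31))]
    spring = df[_window_mask(df["date"], year, (4, 1), (6, 30))]
    n_winter = (date(year, 3, 31) - date(year, 1, 1)).days + 1
    if len(winter) != n_winter or len(spring) != 91:
        raise ValueError(f"incomplete seasonal weather coverage for year {year}")
    tmean_w = (winter["tmin"] + winter["tmax"]) / 2.0
    tmean_s = (spring["tmin"] + spring["tmax"]) / 2.0
    return SeasonCovariates(
        trap_id=trap_id,
        year=year,
        winter_temp=float(tmean_w.mean()),
        spring_temp=float(tmean_s.mean()),
        winter_precip=float(winter["precip"].sum()),
        maize=float(maize),
        year_index=int(year - first_year),
    )


def weekly_z(gdd: pd.DataFrame, week_dates, z_scale: float = 1.0) -> np.ndarray:
    """Cumulative GDD sampled at the weekly trap-reading dates.

    ``z_scale`` multiplies the raw degree-day sums (the emergence model is
    invariant to this rescaling because gamma absorbs it; see the report
    manifest for the factor used in a given run).
    """
    dates = pd.to_datetime(pd.Series(list(week_dates)))
    lookup = gdd.set_index("date")["cumulative_gdd"]
    missing = [d for d in dates if d not in lookup.index]
    if missing:
        raise ValueError(f"reading dates outside GDD coverage: {missing[:3]}")
    z = lookup.loc[dates].to_numpy(dtype=float) * float(z_scale)
    return z


def nearest_station(
    trap_xy: np.ndarray, station_xy: np.ndarray, station_ids
) -> np.ndarray:
    """Assign each trap the id of its nearest station (planar Euclidean distance)."""
    trap_xy = np.asarray(trap_xy, dtype=float)
    station_xy = np.asarray(station_xy, dtype=float)
    d2 = ((trap_xy[:, None, :] - station_xy[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    return np.asarray(list(station_ids))[idx]
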