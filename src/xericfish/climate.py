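"""Annual precipitation and seasonal temperature metrics per site.

Precipitation metrics are computed on calendar years (1 January to 31
December): annual total, anomaly relative to the site's long-term mean
total, count of zero-precipitation days (daily total below 1 mm), and
intensity (annual total divided by the number of rain days).  Temperature
metrics are seasonal means of daily averages ``(tmin + tmax)/2`` plus
anomalies against the long-term seasonal mean.

Seasons follow the meteorological quarters of each hemisphere: in the
north, winter is December-February and summer June-August; in the south the
labels swap (summer December-February, winter June-August).  December is
assigned to the quarter labelled by the following January's year so blocks
stay contiguous.  Long-term means are self-inclusive (the focal year is part
of its own reference), so anomalies over the full record sum to ~0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "daily_mean_temp",
    "season_of",
    "annual_precip_metrics",
    "seasonal_temp_metrics",
    "WET_THRESHOLD_MM",
]

#: a day with less than this much precipitation counts as a zero-precip day
WET_THRESHOLD_MM = 1.0

_NORTH = {12: "winter", 1: "winter", 2: "winter",
          3: "spring", 4: "spring", 5: "spring",
          6: "summer", 7: "summer", 8: "summer",
          9: "fall", 10: "fall", 11: "fall"}
_SWAP = {"winter": "summer", "summer": "winter", "spring": "fall", "fall": "spring"}
_SOUTH = {m: _SWAP[s] for m, s in _NORTH.items()}


def daily_mean_temp(tmin, tmax):
    """Daily average temperature (tmin + tmax) / 2; requires tmax >= tmin."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin encountered")
    return (tmin + tmax) / 2.0


def season_of(month: int, hemisphere: str) -> str:
    """Meteorological season of a month in the given hemisphere."""
    if hemisphere not in ("north", "south"):
        raise ValueError("hemisphere must be 'north' or 'south'")
    table = _NORTH if hemisphere == "north" else _SOUTH
    return table[int(month)]


def _year_coverage_ok(dates: pd.Series, year: int, max_missing_frac: float) -> bool:
    n_days = pd.Timestamp(year=year, month=12, day=31).dayofyear
    have = dates[dates.dt.year == year].dt.normalize().nunique()
    return have >= (1 - max_missing_frac) * n_days


def annual_precip_metrics(daily: pd.DataFrame,
                          wet_threshold: float = WET_THRESHOLD_MM,
                          max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Per-calendar-year precipitation metrics for one site.

    ``daily`` needs columns ``date`` and ``precip`` (mm).  Years with more
    than ``max_missing_frac`` of days missing get NaN metrics (flagged in
    the ``complete`` column) and are excluded from the long-term mean.
    Intensity is NaN for a year without rain days.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if (df["precip"].dropna() < 0).any():
        raise ValueError("negative precipitation")
    df["year"] = df["date"].dt.year
    rows = []
    for year, g in df.groupby("year"):
        ok = _year_coverage_ok(df["date"], int(year), max_missing_frac)
        p = g["precip"].dropna()
        total = float(p.sum())
        zero_days = int((p < wet_threshold).sum())
        rain_days = int((p >= wet_threshold).sum())
        intensity = total / rain_days if rain_days else np.nan
        rows.append(dict(year=int(year), total=total,
                         zero_precip_days=zero_days, rain_days=rain_days,
                         intensity=intensity, complete=ok))
    out = pd.DataFrame(rows).sort_values("year").reset_index(drop=True)
    longterm = out.loc[out["complete"], "total"].mean()
    out["anomaly"] = out["total"] - longterm
    out.loc[~out["complete"],
            ["total", "zero_precip_days", "rain_days", "intensity", "anomaly"]] = np.nan
    return out


def seasonal_temp_metrics(daily: pd.DataFrame, hemisphere: str,
                          max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Per-season temperature means and anomalies for one site.

    ``daily`` needs ``date``, ``tmin``, ``tmax``.  Season blocks are
    contiguous three-month quarters; a December row belongs to the block
    labelled by the following year.  The anomaly of a season-year is its
    mean minus the long-term mean of that season over the record.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["tmean"] = daily_mean_temp(df["tmin"], df["tmax"])
    month = df["date"].dt.month
    df["season"] = [season_of(m, hemisphere) for m in month]
    df["season_year"] = df["date"].dt.year + (month == 12).astype(int)

    n_expected = {  # nominal days per quarter, for the coverage screen
        "winter": 90, "spring": 92, "summer": 92, "fall": 91,
    } if hemisphere == "north" else {
        "summer": 90, "fall": 92, "winter": 92, "spring": 91,
    }
    rows = []
    for (sy, season), g in df.groupby(["season_year", "season"]):
        n = g["tmean"].notna().sum()
        complete = n >= (1 - max_missing_frac) * n_expected[season]
        rows.append(dict(year=int(sy), season=season,
                         mean_temp=float(g["tmean"].mean()),
                         n_days=int(n), complete=bool(complete)))
    out = pd.DataFrame(rows)
    longterm = (out.loc[out["complete"]]
                .groupby("season")["mean_temp"].mean().rename("longterm"))
    out = out.merge(longterm, on="season", how="left")
    out["anomaly"] = out["mean_temp"] - out["longterm"]
    out.loc[~out["complete"], ["mean_temp", "anomaly"]] = np.nan
    return (out.drop(columns="longterm")
            .sort_values(["year", "season"]).reset_index(drop=True))
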