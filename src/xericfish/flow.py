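"""Streamflow intermittency metrics and Fourier-based flow anomalies.

Per water year (1 October–30 September in the USA, 1 July–30 June in
Australia; configurable) three drying metrics are computed from daily gauge
data: the number of zero-flow days, the 1-based day-of-water-year on which
the annual minimum daily discharge first occurs, and the longest run of
consecutive zero-flow days.  A day is *dry* when discharge is zero and
stage height does not contradict it — a zero-discharge day with stage above
``stage_threshold`` is treated as a flow reversal, not a dry channel.  At
the cell level a day is dry when ANY member gauge is dry.

Flow anomalies follow the discrete-Fourier-transform seasonal-baseline
approach: discharge is mean-normalized and log10-transformed,
``z(t) = log10(q(t)/qbar + c)``; the seasonal expectation is rebuilt from
the DFT's zero frequency plus the annual fundamental (period 365.25 d) and
those harmonics (k = 2..max) whose periodogram ordinate exceeds a white-
noise significance threshold.  The residual ``a(t) = z(t) - s(t)`` summed
over a water year is the net annual anomaly (NAA); zero marks a year of
average flow, negative values drier-than-average years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaterYear",
    "dry_day_flags",
    "drying_metrics",
    "seasonal_profile_fft",
    "net_annual_anomaly",
    "SeasonalDecomposition",
    "longest_run",
]


@dataclass(frozen=True)
class WaterYear:
    """Water-year convention: year labelled by its ending calendar year."""

    start_month: int = 10
    start_day: int = 1

    def of(self, dates) -> np.ndarray:
        d = pd.DatetimeIndex(pd.to_datetime(dates))
        after_start = (d.month > self.start_month) | (
            (d.month == self.start_month) & (d.day >= self.start_day)
        )
        if self.start_month == 1 and self.start_day == 1:
            return d.year.to_numpy()
        return (d.year + after_start.astype(int)).to_numpy()


USA_WATER_YEAR = WaterYear(10, 1)
AUS_WATER_YEAR = WaterYear(7, 1)


def dry_day_flags(gauge_days: pd.DataFrame, stage_threshold: float = 0.02):
    """Per-day dry flags for a cell from one or more member gauges.

    ``gauge_days`` has columns ``date``, ``discharge``, ``stage`` and
    optionally ``gauge`` (gauge id; absent means a single gauge).  A gauge-
    day is dry iff discharge == 0 and (stage is missing or
    stage <= stage_threshold); discharge 0 with higher stage is a flow
    reversal and not dry.  The cell is dry on a date iff any gauge reporting
    that date is dry.  Returns a DataFrame with ``date``, ``dry`` (boolean)
    and ``missing`` (no gauge reported discharge).
    """
    df = gauge_days.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    q = df["discharge"]
    stage = df["stage"] if "stage" in df else pd.Series(np.nan, index=df.index)
    gauge_dry = (q == 0) & (stage.isna() | (stage <= stage_threshold))
    df["_dry"] = gauge_dry.astype(float).where(q.notna())
    g = df.groupby("date")["_dry"]
    reported = g.count()
    dry = g.max().fillna(0.0) > 0
    per_day = pd.DataFrame({"date": reported.index,
                            "dry": dry.to_numpy(),
                            "missing": (reported == 0).to_numpy()})
    per_day.loc[per_day["missing"], "dry"] = False
    return per_day


def longest_run(flags) -> int:
    """Length of the longest run of True in a boolean sequence."""
    best = cur = 0
    for f in np.asarray(flags, dtype=bool):
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def drying_metrics(daily: pd.DataFrame, water_year: WaterYear = USA_WATER_YEAR,
                   min_coverage: float = 0.90) -> pd.DataFrame:
    """Per-water-year drying metrics from cell-level daily data.

    ``daily`` needs ``date``, ``discharge`` (cell-level daily discharge,
    e.g. the mean over member gauges) and ``dry`` (from
    :func:`dry_day_flags`).  Water years with less than ``min_coverage``
    daily coverage yield NaN metrics.  ``first_day_min_flow`` is the 1-based
    index, within the water year, of the first day attaining the annual
    minimum discharge.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values("date").reset_index(drop=True)
    df["wy"] = water_year.of(df["date"])
    rows = []
    for wy, g in df.groupby("wy"):
        start = pd.Timestamp(year=int(wy) - 1 if water_year.start_month > 1 else int(wy),
                             month=water_year.start_month, day=water_year.start_day)
        n_days = ((start + pd.DateOffset(years=1)) - start).days
        have = g["discharge"].notna() | g["dry"].notna()
        coverage = have.sum() / n_days
        if coverage < min_coverage:
            rows.append(dict(water_year=int(wy), zero_flow_days=np.nan,
                             first_day_min_flow=np.nan,
                             max_no_flow_duration=np.nan,
                             coverage=float(coverage)))
            continue
        dry = g["dry"].fillna(False).to_numpy(bool)
        q = g["discharge"].to_numpy(float)
        day_index = (g["date"] - start).dt.days.to_numpy() + 1  # 1-based
        qmin = np.nanmin(q)
        first_min = int(day_index[int(np.flatnonzero(q == qmin)[0])])
        rows.append(dict(water_year=int(wy),
                         zero_flow_days=int(dry.sum()),
                         first_day_min_flow=first_min,
                         max_no_flow_duration=int(longest_run(dry)),
                         coverage=float(coverage)))
    return pd.DataFrame(rows)


@dataclass
class SeasonalDecomposition:
    """Log-discharge series split into a Fourier seasonal baseline and residuals."""

    z: np.ndarray                  # log10(q/qbar + c)
    seasonal: np.ndarray           # reconstructed seasonal expectation
    anomaly: np.ndarray            # z - seasonal
    retained_harmonics: list[int]  # harmonic numbers kept (1 = fundamental)
    retained_bins: list[int] = field(default_factory=list)
    log_offset: float = 0.01


def seasonal_profile_fft(discharge, log_offset: float = 0.01,
                         period: float = 365.25, max_harmonics: int = 6,
                         alpha: float = 0.05) -> SeasonalDecomposition:
    """Fit the Fourier seasonal baseline to a daily discharge series.

    The fundamental annual frequency is always retained; harmonics
    ``k = 2..max_harmonics`` are retained when their periodogram ordinate
    exceeds the white-noise exceedance threshold ``-m ln(alpha)``, where
    ``m`` is a robust (median-based) estimate of the background ordinate.
    Requires at least two full years of data.
    """
    q = np.asarray(discharge, dtype=float)
    n = q.size
    if n < 2 * 365:
        raise ValueError("need at least two full years of daily data")
    if np.any(q < 0):
        raise ValueError("negative discharge")
    z = np.log10(q / q.mean() + log_offset)

    spec = np.fft.rfft(z)
    power = np.abs(spec) ** 2
    candidates = {}
    for k in range(1, max_harmonics + 1):
        b = int(round(k * n / period))
        if 0 < b < len(spec):
            candidates[k] = b

    # background level from the median ordinate away from candidate bins
    mask = np.ones(len(power), dtype=bool)
    mask[0] = False
    for b in candidates.values():
        mask[max(b - 1, 0):b + 2] = False
    background = np.median(power[mask]) / np.log(2.0)  # median of Exp(m) = m ln 2
    threshold = -background * np.log(alpha)

    keep = np.zeros(len(spec), dtype=bool)
    keep[0] = True  # mean
    retained, bins = [], []
    for k, b in candidates.items():
        if k == 1 or power[b] > threshold:
            keep[b] = True
            retained.append(k)
            bins.append(b)
    seasonal = np.fft.irfft(np.where(keep, spec, 0.0), n=n)
    return SeasonalDecomposition(z=z, seasonal=seasonal, anomaly=z - seasonal,
                                 retained_harmonics=retained,
                                 retained_bins=bins, log_offset=log_offset)


def net_annual_anomaly(anomaly, dates,
                       water_year: WaterYear = USA_WATER_YEAR) -> pd.DataFrame:
    """Net annual anomaly: the daily anomalies summed per water year."""
    a = np.asarray(anomaly, dtype=float)
    wy = water_year.of(dates)
    df = pd.DataFrame({"water_year": wy, "a": a})
    out = df.groupby("water_year")["a"].agg(naa="sum", n_days="size").reset_index()
    return out
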