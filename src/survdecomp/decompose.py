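"""Additive decomposition of a quarterly count series.

The model is y_t = TR_t + SV_t + i_t with the irregular term taken as
zero, so the seasonal variation is simply the observation minus the
moving-average trend:

* ``moving_average_trend`` -- centered odd-window arithmetic mean
  (default window 3), undefined at the first and last floor(window/2)
  quarters;
* ``seasonal_variation`` -- SV_t = y_t - TR_t at every trend-bearing
  quarter;
* ``quarterly_seasonal_averages`` -- the SV values pooled by calendar
  quarter and averaged. ``divisor_mode="standard"`` divides by the number
  of values (the textbook seasonal-index convention);
  ``divisor_mode="paper"`` divides by (count - 1), the convention used in
  the source analysis this package reproduces;
* ``adjust_seasonal_factors`` -- subtracts the mean of the four averages
  so the adjusted factors sum to zero.

Note the 3-term window does not fully cancel period-4 seasonality, so a
little seasonal signal leaks into the trend; the zero-sum adjustment
still guarantees the factors are a pure seasonal contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .series import QuarterPeriod, QuarterlyCaseSeries

DivisorMode = Literal["paper", "standard"]


@dataclass(frozen=True)
class TrendSeries:
    """Moving-average trend TR_t, defined on the interior quarters only."""

    periods: tuple[QuarterPeriod, ...]
    values: np.ndarray
    window: int = 3

    def __len__(self) -> int:
        return len(self.periods)


@dataclass(frozen=True)
class SeasonalVariationTable:
    """SV_t = y_t - TR_t for each trend-bearing quarter."""

    periods: tuple[QuarterPeriod, ...]
    values: np.ndarray


@dataclass(frozen=True)
class SeasonalFactorSet:
    """Raw per-quarter SV averages and their zero-sum adjustment.

    ``raw_averages`` and ``adjusted_factors`` are indexed by calendar
    quarter 1..4; ``correction`` is the mean of the raw averages, and
    ``adjusted_factors[q] = raw_averages[q] - correction``.
    """

    raw_averages: dict[int, float]
    correction: float
    adjusted_factors: dict[int, float]
    divisor_mode: DivisorMode = "paper"

    def factor(self, quarter: int) -> float:
        return self.adjusted_factors[quarter]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quarter": [1, 2, 3, 4],
                "raw_average": [self.raw_averages[q] for q in (1, 2, 3, 4)],
                "correction": [self.correction] * 4,
                "adjusted_factor": [self.adjusted_factors[q] for q in (1, 2, 3, 4)],
                "divisor_mode": [self.divisor_mode] * 4,
            }
        )


def moving_average_trend(series: QuarterlyCaseSeries, window: int = 3) -> TrendSeries:
    """Centered moving-average trend of the counts.

    The value at an interior quarter is the arithmetic mean of the
    ``window`` counts centered there; the first and last floor(window/2)
    quarters carry no value.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if len(series) < window:
        raise InsufficientDataError(
            f"series of length {len(series)} shorter than window {window}"
        )
    half = window // 2
    counts = series.counts.astype(float)
    # mean of each length-`window` sliding block
    values = np.convolve(counts, np.ones(window) / window, mode="valid")
    return TrendSeries(
        periods=series.periods[half : len(series) - half],
        values=values,
        window=window,
    )


def seasonal_variation(
    series: QuarterlyCaseSeries, trend: TrendSeries
) -> SeasonalVariationTable:
    """SV_t = y_t - TR_t on exactly the trend-bearing quarters."""
    index = {p: c for p, c in zip(series.periods, series.counts)}
    try:
        observed = np.array([index[p] for p in trend.periods], dtype=float)
    except KeyError as exc:
        raise ValueError(f"trend period {exc.args[0]} absent from series") from exc
    return SeasonalVariationTable(periods=trend.periods, values=observed - trend.values)


def quarterly_seasonal_averages(
    sv: SeasonalVariationTable, divisor_mode: DivisorMode = "paper"
) -> dict[int, float]:
    """Average the seasonal variations by calendar quarter.

    ``standard`` divides each quarter's SV total by the number of values;
    ``paper`` divides by (number of values - 1) and therefore requires at
    least two values per quarter.
    """
    if divisor_mode not in ("paper", "standard"):
        raise ValueError(f"unknown divisor_mode {divisor_mode!r}")
    pools: dict[int, list[float]] = {1: [], 2: [], 3: [], 4: []}
    for period, value in zip(sv.periods, sv.values):
        pools[period.quarter].append(float(value))
    averages: dict[int, float] = {}
    for quarter, values in pools.items():
        if not values:
            raise InsufficientDataError(f"no seasonal variation for quarter {quarter}")
        divisor = len(values) - 1 if divisor_mode == "paper" else len(values)
        if divisor == 0:
            raise InsufficientDataError(
                f"paper divisor mode needs >= 2 values for quarter {quarter}"
            )
        averages[quarter] = sum(values) / divisor
    return averages


def adjust_seasonal_factors(
    raw_averages: Mapping[int, float], divisor_mode: DivisorMode = "paper"
) -> SeasonalFactorSet:
    """Mean-center the four quarterly averages so they sum to zero."""
    values = [float(raw_averages[q]) for q in (1, 2, 3, 4)]
    if not np.all(np.isfinite(values)):
        raise ValueError("seasonal averages must be finite")
    correction = float(np.mean(values))
    adjusted = {q: float(raw_averages[q]) - correction for q in (1, 2, 3, 4)}
    return SeasonalFactorSet(
        raw_averages={q: float(raw_averages[q]) for q in (1, 2, 3, 4)},
        correction=correction,
        adjusted_factors=adjusted,
        divisor_mode=divisor_mode,
    )


def seasonal_factors(
    series: QuarterlyCaseSeries,
    window: int = 3,
    divisor_mode: DivisorMode = "paper",
) -> SeasonalFactorSet:
    """Convenience: trend -> SV -> quarterly averages -> zero-sum factors."""
    trend = moving_average_trend(series, window)
    sv = seasonal_variation(series, trend)
    return adjust_seasonal_factors(
        quarterly_seasonal_averages(sv, divisor_mode), divisor_mode
    )


def decomposition_frame(
    series: QuarterlyCaseSeries, trend: TrendSeries, sv: SeasonalVariationTable
) -> pd.DataFrame:
    """One row per observed quarter: count, trend and SV (NaN at endpoints)."""
    trend_map = {p: v for p, v in zip(trend.periods, trend.values)}
    sv_map = {p: v for p, v in zip(sv.periods, sv.values)}
    return pd.DataFrame(
        {
            "year": [p.year for p in series.periods],
            "quarter": [p.quarter for p in series.periods],
            "cases": series.counts,
            "trend": [trend_map.get(p, np.nan) for p in series.periods],
            "seasonal_variation": [sv_map.get(p, np.nan) for p in series.periods],
        }
    )
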