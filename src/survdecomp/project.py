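"""Linear extrapolation of the moving-average trend with seasonal re-addition.

The trend slope is the "increase in trend line per quarter" (ITLPQ):
(last trend value - first trend value) / (number of trend values - 1).
Each projected quarter k beyond the last trend-bearing quarter gets an
extrapolated trend last + k*ITLPQ, re-adds the zero-sum seasonal factor
of its calendar quarter, and is rounded half-up to an integer case
count. The confidence interval is a count-based normal interval,
round(P +/- z*sqrt(P)) computed from the rounded point projection P --
i.e. a Poisson-variance approximation on the projected count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .decompose import SeasonalFactorSet, TrendSeries
from .errors import InsufficientDataError
from .series import QuarterPeriod

_ZERO_SUM_TOL = 1e-6


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TrendSlope:
    """Linear per-quarter slope of the moving-average trend (ITLPQ)."""

    itlpq: float
    first_trend: float
    last_trend: float
    n_trend_values: int


@dataclass(frozen=True)
class ProjectionRow:
    period: QuarterPeriod
    extrapolated_trend: float
    seasonal_factor: float
    projection: int
    ci_low: int
    ci_high: int
    ci_level: float = 0.95


@dataclass(frozen=True)
class ProjectionTable:
    rows: tuple[ProjectionRow, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [r.period.year for r in self.rows],
                "quarter": [r.period.quarter for r in self.rows],
                "extrapolated_trend": [r.extrapolated_trend for r in self.rows],
                "seasonal_factor": [r.seasonal_factor for r in self.rows],
                "projection": [r.projection for r in self.rows],
                "ci_low": [r.ci_low for r in self.rows],
                "ci_high": [r.ci_high for r in self.rows],
            }
        )


@dataclass(frozen=True)
class YearTotal:
    """Annual sum of quarterly projections; partial years are flagged."""

    total: int
    n_quarters: int

    @property
    def partial(self) -> bool:
        return self.n_quarters < 4


def compute_itlpq(trend: TrendSeries) -> TrendSlope:
    """Slope of the trend line: (last - first) / (count - 1)."""
    n = len(trend)
    if n < 2:
        raise InsufficientDataError("need at least 2 trend values for a slope")
    first = float(trend.values[0])
    last = float(trend.values[-1])
    return TrendSlope(
        itlpq=(last - first) / (n - 1),
        first_trend=first,
        last_trend=last,
        n_trend_values=n,
    )


def project(
    slope: TrendSlope,
    last_trend_period: QuarterPeriod,
    factors: SeasonalFactorSet,
    horizon: int,
    ci_level: float = 0.95,
) -> ProjectionTable:
    """Project ``horizon`` quarters beyond the last trend-bearing quarter.

    The first projected quarter immediately follows ``last_trend_period``;
    when the source series extends one quarter past the trend (as the
    centered window forces), that first row is in-sample and doubles as a
    sanity check against the observation.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if abs(sum(factors.adjusted_factors.values())) > _ZERO_SUM_TOL:
        raise ValueError("seasonal factors must be zero-sum adjusted before projection")
    z = float(stats.norm.ppf(0.5 + ci_level / 2))
    rows = []
    period = last_trend_period
    for k in range(1, horizon + 1):
        period = period.successor()
        trend_k = slope.last_trend + k * slope.itlpq
        factor = factors.factor(period.quarter)
        point = round_half_up(trend_k + factor)
        if point < 0:
            warnings.warn(
                f"negative projection at {period} floored to 0", stacklevel=2
            )
            point = 0
        half_width = z * math.sqrt(point)
        low = max(0, round_half_up(point - half_width))
        high = round_half_up(point + half_width)
        rows.append(
            ProjectionRow(
                period=period,
                extrapolated_trend=trend_k,
                seasonal_factor=factor,
                projection=point,
                ci_low=low,
                ci_high=high,
                ci_level=ci_level,
            )
        )
    return ProjectionTable(rows=tuple(rows))


def annual_totals(table: ProjectionTable) -> dict[int, YearTotal]:
    """Sum quarterly projections per calendar year, flagging partial years."""
    sums: dict[int, int] = {}
    counts: dict[int, int] = {}
    for row in table.rows:
        sums[row.period.year] = sums.get(row.period.year, 0) + row.projection
        counts[row.period.year] = counts.get(row.period.year, 0) + 1
    return {
        year: YearTotal(total=sums[year], n_quarters=counts[year])
        for year in sorted(sums)
    }
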