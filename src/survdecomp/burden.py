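"""Descriptive burden statistics: case shares and case fatality rates.

The case fatality rate (CFR) of a stratum is 100*deaths/cases. Its
confidence interval is, by default, the normal-approximation (Wald)
binomial interval 100*(p +/- z*sqrt(p(1-p)/n)) clamped to [0, 100];
the exact Clopper-Pearson interval is available as a cross-check and is
never narrower. Interval arithmetic is delegated to
``statsmodels.stats.proportion.proportion_confint``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import NoDataError
from .series import AgeStratumRecord, QuarterlyCaseSeries

CfrMethod = Literal["wald", "exact"]

_METHOD_MAP = {"wald": "normal", "exact": "beta"}


@dataclass(frozen=True)
class CfrResult:
    """Case fatality rate of one age stratum, in percent, with its CI."""

    label: str
    cases: int
    deaths: int
    cfr: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    method: CfrMethod = "wald"


def case_fatality_rate(
    stratum: AgeStratumRecord,
    ci_level: float = 0.95,
    method: CfrMethod = "wald",
) -> CfrResult:
    """CFR and binomial CI for one stratum; ``cases`` must be >= 1."""
    if stratum.cases == 0:
        raise NoDataError(f"{stratum.label}: cannot compute CFR with zero cases")
    if method not in _METHOD_MAP:
        raise ValueError(f"unknown CFR method {method!r}")
    low, high = proportion_confint(
        stratum.deaths, stratum.cases, alpha=1 - ci_level, method=_METHOD_MAP[method]
    )
    low = float(np.nan_to_num(low, nan=0.0))
    high = float(np.nan_to_num(high, nan=0.0))
    return CfrResult(
        label=stratum.label,
        cases=stratum.cases,
        deaths=stratum.deaths,
        cfr=100.0 * stratum.deaths / stratum.cases,
        ci_low=float(np.clip(100.0 * low, 0.0, 100.0)),
        ci_high=float(np.clip(100.0 * high, 0.0, 100.0)),
        ci_level=ci_level,
        method=method,
    )


def distribution_shares(strata: Sequence[AgeStratumRecord]) -> dict[str, float]:
    """Percentage of total cases per age group (full precision)."""
    total = sum(s.cases for s in strata)
    if total == 0:
        raise NoDataError("total cases is zero; shares undefined")
    return {s.label: 100.0 * s.cases / total for s in strata}


def annual_shares(series: QuarterlyCaseSeries) -> dict[int, tuple[int, float]]:
    """Per-year case totals and their percentage of the grand total."""
    sums: dict[int, int] = {}
    for period, count in zip(series.periods, series.counts):
        sums[period.year] = sums.get(period.year, 0) + int(count)
    grand = series.total
    return {
        year: (sums[year], 100.0 * sums[year] / grand) for year in sorted(sums)
    }
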