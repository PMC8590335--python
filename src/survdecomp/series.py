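"""Core domain containers: calendar quarters, quarterly count series, age strata.

A :class:`QuarterPeriod` is a (year, quarter) pair with Q1 = Jan-Mar ...
Q4 = Oct-Dec and lexicographic ordering; the successor of (y, 4) is
(y+1, 1). A :class:`QuarterlyCaseSeries` is a gap-free, chronologically
ordered run of such quarters with one non-negative integer case count
each -- the observed y_t of the additive model y_t = TR_t + SV_t + i_t.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicatePeriodError,
    InvalidCountError,
    InvalidPeriodError,
    NoDataError,
    PeriodGapError,
    StratumConsistencyError,
)

_COMBINED_TOKEN = re.compile(r"^\s*(\d{4})\s*[-_ ]?\s*[Qq]\s*([1-4])\s*$")


@dataclass(frozen=True, order=True)
class QuarterPeriod:
    """A calendar quarter, totally ordered by (year, quarter)."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if not (isinstance(self.year, (int, np.integer)) and self.year >= 1900):
            raise InvalidPeriodError(f"year must be an integer >= 1900, got {self.year!r}")
        if self.quarter not in (1, 2, 3, 4):
            raise InvalidPeriodError(f"quarter must be in 1..4, got {self.quarter!r}")

    def successor(self) -> "QuarterPeriod":
        if self.quarter == 4:
            return QuarterPeriod(self.year + 1, 1)
        return QuarterPeriod(self.year, self.quarter + 1)

    @classmethod
    def parse(cls, token: str) -> "QuarterPeriod":
        """Parse a combined token such as ``2013-Q1``, ``2013Q1`` or ``2013 q1``."""
        m = _COMBINED_TOKEN.match(str(token))
        if m is None:
            raise InvalidPeriodError(f"cannot parse quarter token {token!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.year}-Q{self.quarter}"


def _validate_count(value: object, context: str) -> int:
    """Accept only non-negative integer tallies; reject decimals outright."""
    if isinstance(value, (bool, np.bool_)):
        raise InvalidCountError(f"{context}: boolean is not a count")
    if isinstance(value, (float, np.floating)):
        if not float(value).is_integer():
            raise InvalidCountError(f"{context}: count {value!r} is not an integer")
        value = int(value)
    if isinstance(value, str):
        try:
            value = int(value)
        except ValueError as exc:
            raise InvalidCountError(f"{context}: count {value!r} is not an integer") from exc
    if not isinstance(value, (int, np.integer)):
        raise InvalidCountError(f"{context}: count {value!r} is not an integer")
    if value < 0:
        raise InvalidCountError(f"{context}: count {value} is negative")
    return int(value)


@dataclass(frozen=True)
class QuarterlyCaseSeries:
    """Gap-free chronological quarterly case counts (the observed y_t)."""

    periods: tuple[QuarterPeriod, ...]
    counts: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.periods) == 0:
            raise NoDataError("series contains no quarters")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.periods),):
            raise InvalidCountError("one count per period required")
        validated = np.array(
            [_validate_count(c, str(p)) for p, c in zip(self.periods, counts)],
            dtype=np.int64,
        )
        object.__setattr__(self, "counts", validated)
        object.__setattr__(self, "periods", tuple(self.periods))
        seen = set()
        for p in self.periods:
            if p in seen:
                raise DuplicatePeriodError(f"duplicate period {p}")
            seen.add(p)
        for a, b in zip(self.periods, self.periods[1:]):
            if b != a.successor():
                raise PeriodGapError(f"gap in periods between {a} and {b}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, int, object]]
    ) -> "QuarterlyCaseSeries":
        """Build a series from (year, quarter, count) rows in any order."""
        rows = sorted(records, key=lambda r: (r[0], r[1]))
        if not rows:
            raise NoDataError("no data rows")
        periods = tuple(QuarterPeriod(int(y), int(q)) for y, q, _ in rows)
        counts = np.array([c for _, _, c in rows], dtype=object)
        return cls(periods=periods, counts=counts)

    def __len__(self) -> int:
        return len(self.periods)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [p.year for p in self.periods],
                "quarter": [p.quarter for p in self.periods],
                "cases": self.counts,
            }
        )


@dataclass(frozen=True)
class AgeStratumRecord:
    """Cases and deaths for one age group of the surveillance population."""

    label: str
    cases: int
    deaths: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", _validate_count(self.cases, self.label))
        object.__setattr__(self, "deaths", _validate_count(self.deaths, self.label))
        if self.deaths > self.cases:
            raise StratumConsistencyError(
                f"{self.label}: deaths ({self.deaths}) exceed cases ({self.cases})"
            )


def strata_to_frame(strata: Sequence[AgeStratumRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_group": [s.label for s in strata],
            "cases": [s.cases for s in strata],
            "deaths": [s.deaths for s in strata],
        }
    )
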