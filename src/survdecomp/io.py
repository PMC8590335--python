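"""CSV readers and writers for quarterly count and age-stratum tables.

Input schema #1 (quarterly counts): columns ``year, quarter, cases``.
The quarter may also be supplied as a single combined column (``period``
or ``quarter`` holding tokens like ``2013-Q1``), as both layouts occur in
surveillance exports. Input schema #2 (age strata): columns
``age_group, cases, deaths``. Loaders are row-order insensitive and
validate eagerly; all failures raise the named errors in
:mod:`survdecomp.errors`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import MissingColumnError, NoDataError
from .series import AgeStratumRecord, QuarterPeriod, QuarterlyCaseSeries


@dataclass(frozen=True)
class CsvDialect:
    """Configurable header names for the quarterly-count CSV."""

    year_col: str = "year"
    quarter_col: str = "quarter"
    cases_col: str = "cases"
    sep: str = ","


def _read_csv(path: os.PathLike | str, sep: str = ",") -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=sep, dtype=object)
    except pd.errors.EmptyDataError as exc:
        raise NoDataError(f"{path}: no data") from exc
    if frame.empty and frame.columns.empty:
        raise NoDataError(f"{path}: no data")
    return frame


def load_quarterly_series(
    path: os.PathLike | str, dialect: CsvDialect | None = None
) -> QuarterlyCaseSeries:
    """Read, validate and chronologically sort a quarterly case-count CSV."""
    dialect = dialect or CsvDialect()
    frame = _read_csv(path, dialect.sep)
    cols = set(frame.columns)
    records: list[tuple[int, int, object]] = []
    if {dialect.year_col, dialect.quarter_col, dialect.cases_col} <= cols:
        for _, row in frame.iterrows():
            q = row[dialect.quarter_col]
            if isinstance(q, str) and not q.strip().isdigit():
                period = QuarterPeriod.parse(q)
            else:
                period = QuarterPeriod(int(row[dialect.year_col]), int(q))
            records.append((period.year, period.quarter, row[dialect.cases_col]))
    elif dialect.cases_col in cols and ({"period"} & cols or {dialect.quarter_col} & cols):
        token_col = "period" if "period" in cols else dialect.quarter_col
        for _, row in frame.iterrows():
            period = QuarterPeriod.parse(row[token_col])
            records.append((period.year, period.quarter, row[dialect.cases_col]))
    else:
        missing = {dialect.year_col, dialect.quarter_col, dialect.cases_col} - cols
        raise MissingColumnError(f"{path}: missing column(s) {sorted(missing)}")
    if not records:
        raise NoDataError(f"{path}: no data rows")
    return QuarterlyCaseSeries.from_records(records)


def load_age_strata(path: os.PathLike | str) -> list[AgeStratumRecord]:
    """Read and validate an age-stratified cases/deaths CSV, order preserved."""
    frame = _read_csv(path)
    required = {"age_group", "cases", "deaths"}
    missing = required - set(frame.columns)
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        AgeStratumRecord(label=str(row["age_group"]), cases=row["cases"], deaths=row["deaths"])
        for _, row in frame.iterrows()
    ]


def write_table(table, path: os.PathLike | str, format: str = "csv") -> None:
    """Write any result table to disk at full numeric precision.

    Accepts a :class:`pandas.DataFrame` or any object exposing
    ``to_frame()``. Display rounding is the report layer's concern.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    frame.to_csv(path, index=False)


def write_quarterly_series(
    series: QuarterlyCaseSeries, path: os.PathLike | str
) -> None:
    write_table(series.to_frame(), path)


def write_age_strata(strata: Sequence[AgeStratumRecord], path: os.PathLike | str) -> None:
    from .series import strata_to_frame

    write_table(strata_to_frame(strata), path)
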