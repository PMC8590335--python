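"""Packaged example data: Plateau State under-five diarrhoea surveillance.

Twenty quarterly case counts (2013 Q1 - 2017 Q4) and three age strata
(cases/deaths) aggregated from Nigeria's IDSR routine reporting, as
published for Plateau State. These small tables let every stage of the
pipeline run and be demonstrated without access to the restricted line
data.
"""

from __future__ import annotations

from importlib import resources

from .io import load_age_strata, load_quarterly_series
from .series import AgeStratumRecord, QuarterlyCaseSeries


def _data_path(name: str):
    return resources.files("survdecomp").joinpath("data", name)


def plateau_quarterly_path():
    """Filesystem path of the packaged quarterly-count CSV."""
    return _data_path("plateau_quarterly_cases.csv")


def plateau_strata_path():
    """Filesystem path of the packaged age-stratum CSV."""
    return _data_path("plateau_age_strata.csv")


def load_plateau_quarterly() -> QuarterlyCaseSeries:
    """The 20-quarter Plateau State series (total 60,935 cases)."""
    with resources.as_file(plateau_quarterly_path()) as path:
        return load_quarterly_series(path)


def load_plateau_age_strata() -> list[AgeStratumRecord]:
    """The three Plateau State age strata (132 deaths among 60,935 cases)."""
    with resources.as_file(plateau_strata_path()) as path:
        return load_age_strata(path)
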