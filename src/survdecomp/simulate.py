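"""Synthetic quarterly surveillance series with known trend and seasonality.

The generator draws from the same additive form the decomposition
assumes: a linear trend (base level + slope per quarter), a zero-sum
period-4 seasonal contrast, and one of three noise models (none,
Gaussian, Poisson). Counts are rounded to integers and floored at zero,
which slightly biases very low-count simulations upward -- acceptable
for surveillance-scale levels (thousands of cases per quarter).

Defaults mirror the fitted Plateau State series: base level ~2300 cases,
slope ~87 cases/quarter, factors ~(222, -400, 500, -322).

``recover_parameters`` closes the loop: it runs the full decomposition
on a simulated series and reports estimation error against the known
truth. Because a 3-term moving average does not annihilate period-4
seasonality, some seasonal signal leaks into the trend; slope recovery
is good while factor recovery is only approximate even without noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .decompose import (
    DivisorMode,
    adjust_seasonal_factors,
    moving_average_trend,
    quarterly_seasonal_averages,
    seasonal_variation,
)
from .errors import InsufficientDataError
from .project import compute_itlpq
from .series import QuarterPeriod, QuarterlyCaseSeries

NoiseModel = Literal["none", "gaussian", "poisson"]

_ZERO_SUM_TOL = 1e-9
# Poisson means are floored here so a deterministic mean <= 0 stays drawable
_MIN_POISSON_MEAN = 1e-9


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of a synthetic quarterly series."""

    base_level: float = 2300.0
    slope: float = 87.0
    seasonal_factors: tuple[float, float, float, float] = (222.0, -400.0, 500.0, -322.0)
    noise_model: NoiseModel = "none"
    noise_sd: float = 50.0
    n_years: int = 5
    start: QuarterPeriod = field(default_factory=lambda: QuarterPeriod(2013, 1))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_level < 0:
            raise ValueError("base_level must be >= 0")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if abs(sum(self.seasonal_factors)) > _ZERO_SUM_TOL:
            raise ValueError("seasonal_factors must sum to 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class SimulationResult:
    series: QuarterlyCaseSeries
    truth: SimulationConfig


@dataclass(frozen=True)
class RecoveryReport:
    """Decomposition estimates on a simulated series, scored against truth."""

    itlpq: float
    slope_error: float
    factors: dict[int, float]
    factor_errors: dict[int, float]
    divisor_mode: DivisorMode


def deterministic_mean(config: SimulationConfig, t: int) -> float:
    """Noise-free expected count at quarter offset t (0-based from start)."""
    quarter = ((config.start.quarter - 1 + t) % 4) + 1
    return config.base_level + config.slope * t + config.seasonal_factors[quarter - 1]


def generate_series(config: SimulationConfig) -> SimulationResult:
    """Draw one synthetic series; a pure function of the config (seeded)."""
    rng = np.random.default_rng(config.seed)
    n = 4 * config.n_years
    means = np.array([deterministic_mean(config, t) for t in range(n)])
    if config.noise_model == "none":
        raw = means
    elif config.noise_model == "gaussian":
        raw = means + rng.normal(0.0, config.noise_sd, size=n)
    else:  # poisson: the deterministic mean is the rate
        raw = rng.poisson(np.maximum(means, _MIN_POISSON_MEAN), size=n).astype(float)
    counts = np.maximum(0, np.floor(raw + 0.5)).astype(np.int64)
    periods = [config.start]
    for _ in range(n - 1):
        periods.append(periods[-1].successor())
    series = QuarterlyCaseSeries(periods=tuple(periods), counts=counts)
    return SimulationResult(series=series, truth=config)


def recover_parameters(
    result: SimulationResult, divisor_mode: DivisorMode = "paper"
) -> RecoveryReport:
    """Run the full decomposition on a simulated series and score it."""
    series = result.series
    if len(series) < 12:
        raise InsufficientDataError("need >= 12 quarters for parameter recovery")
    trend = moving_average_trend(series)
    sv = seasonal_variation(series, trend)
    factors = adjust_seasonal_factors(
        quarterly_seasonal_averages(sv, divisor_mode), divisor_mode
    )
    slope = compute_itlpq(trend)
    truth = result.truth
    factor_errors = {
        q: factors.adjusted_factors[q] - truth.seasonal_factors[q - 1]
        for q in (1, 2, 3, 4)
    }
    return RecoveryReport(
        itlpq=slope.itlpq,
        slope_error=slope.itlpq - truth.slope,
        factors=dict(factors.adjusted_factors),
        factor_errors=factor_errors,
        divisor_mode=divisor_mode,
    )
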