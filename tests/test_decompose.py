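"""Decomposition: moving-average trend, seasonal variation, factor adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survdecomp import (
    QuarterPeriod,
    QuarterlyCaseSeries,
    adjust_seasonal_factors,
    moving_average_trend,
    quarterly_seasonal_averages,
    seasonal_variation,
)
from survdecomp.errors import InsufficientDataError

from conftest import (
    PUBLISHED_CORRECTION,
    PUBLISHED_FACTORS,
    PUBLISHED_Q_AVERAGES,
    PUBLISHED_SV,
    PUBLISHED_TREND,
    ma_oracle,
)


def make_series(counts, start=QuarterPeriod(2013, 1)):
    periods = [start]
    for _ in range(len(counts) - 1):
        periods.append(periods[-1].successor())
    return QuarterlyCaseSeries(periods=tuple(periods), counts=np.asarray(counts, dtype=object))


class TestMovingAverageTrend:
    def test_reproduces_published_trend_column(self, plateau_series):
        trend = moving_average_trend(plateau_series)
        assert len(trend) == 18
        assert trend.periods[0] == QuarterPeriod(2013, 2)
        assert trend.periods[-1] == QuarterPeriod(2017, 3)
        np.testing.assert_allclose(trend.values, PUBLISHED_TREND, atol=0.005)

    def test_constant_series_trend_is_constant(self):
        trend = moving_average_trend(make_series([7] * 8))
        np.testing.assert_allclose(trend.values, 7.0)

    def test_matches_brute_force_oracle_on_all_small_lengths(self, rng):
        # exhaustive over lengths 3..12, several random draws each
        for n in range(3, 13):
            for _ in range(5):
                counts = rng.integers(0, 5000, size=n).tolist()
                trend = moving_average_trend(make_series(counts))
                np.testing.assert_allclose(trend.values, ma_oracle(counts), atol=1e-9)

    def test_wider_window(self):
        counts = [10, 20, 30, 40, 50, 60, 70]
        trend = moving_average_trend(make_series(counts), window=5)
        np.testing.assert_allclose(trend.values, [30, 40, 50])

    def test_too_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            moving_average_trend(make_series([1, 2]))

    @pytest.mark.parametrize("window", [2, 4, 1])
    def test_even_or_tiny_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_average_trend(make_series([1] * 10), window=window)

    def test_trend_within_window_bounds(self, rng):
        counts = rng.integers(0, 1000, size=16).tolist()
        trend = moving_average_trend(make_series(counts))
        for i, v in enumerate(trend.values):
            window = counts[i : i + 3]
            assert min(window) <= v <= max(window)


class TestSeasonalVariation:
    def test_reproduces_published_sv_column(self, plateau_series):
        trend = moving_average_trend(plateau_series)
        sv = seasonal_variation(plateau_series, trend)
        np.testing.assert_allclose(sv.values, PUBLISHED_SV, atol=0.005)

    def test_reconstruction_identity(self, plateau_series):
        # TR_t + SV_t must return the observation exactly
        trend = moving_average_trend(plateau_series)
        sv = seasonal_variation(plateau_series, trend)
        observed = dict(zip(plateau_series.periods, plateau_series.counts))
        for p, tr, s in zip(trend.periods, trend.values, sv.values):
            assert tr + s == pytest.approx(observed[p], abs=1e-9)

    def test_pure_linear_series_has_zero_variation(self):
        counts = [100 + 13 * t for t in range(12)]
        series = make_series(counts)
        sv = seasonal_variation(series, moving_average_trend(series))
        np.testing.assert_allclose(sv.values, 0.0, atol=1e-9)

    def test_mismatched_trend_rejected(self, plateau_series):
        other = make_series([1, 2, 3, 4], start=QuarterPeriod(1999, 1))
        trend = moving_average_trend(other)
        with pytest.raises(ValueError):
            seasonal_variation(plateau_series, trend)


class TestQuarterlyAverages:
    @pytest.fixture
    def plateau_sv(self, plateau_series):
        trend = moving_average_trend(plateau_series)
        return seasonal_variation(plateau_series, trend)

    def test_paper_divisor_reproduces_published_averages(self, plateau_sv):
        averages = quarterly_seasonal_averages(plateau_sv, "paper")
        for q, expected in PUBLISHED_Q_AVERAGES.items():
            # printed at 3-4 dp depending on the cell
            assert averages[q] == pytest.approx(expected, abs=0.0005)

    def test_standard_divisor_hand_check(self, plateau_sv):
        averages = quarterly_seasonal_averages(plateau_sv, "standard")
        # Q1 pools 4 values totalling 693.6667 -> 173.4167
        assert averages[1] == pytest.approx(173.4167, abs=0.0005)

    def test_all_zero_variations_average_to_zero(self):
        series = make_series([50 + 3 * t for t in range(16)])
        sv = seasonal_variation(series, moving_average_trend(series))
        for mode in ("paper", "standard"):
            averages = quarterly_seasonal_averages(sv, mode)
            assert all(abs(a) < 1e-9 for a in averages.values())

    def test_paper_mode_needs_two_values_per_quarter(self):
        series = make_series([10, 20, 30, 40, 50, 60])  # one SV per quarter at most
        sv = seasonal_variation(series, moving_average_trend(series))
        with pytest.raises(InsufficientDataError):
            quarterly_seasonal_averages(sv, "paper")

    def test_unknown_mode_rejected(self, plateau_sv):
        with pytest.raises(ValueError):
            quarterly_seasonal_averages(plateau_sv, "bogus")


class TestAdjustment:
    def test_reproduces_published_correction_and_factors(self, plateau_series):
        trend = moving_average_trend(plateau_series)
        sv = seasonal_variation(plateau_series, trend)
        factors = adjust_seasonal_factors(quarterly_seasonal_averages(sv, "paper"))
        assert factors.correction == pytest.approx(PUBLISHED_CORRECTION, abs=5e-7)
        for q, expected in PUBLISHED_FACTORS.items():
            assert factors.adjusted_factors[q] == pytest.approx(expected, abs=0.0005)

    def test_zero_sum_averages_unchanged(self):
        factors = adjust_seasonal_factors({1: 5.0, 2: -5.0, 3: 2.0, 4: -2.0})
        assert factors.correction == 0.0
        assert factors.adjusted_factors == {1: 5.0, 2: -5.0, 3: 2.0, 4: -2.0}

    @settings(max_examples=500)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=4, max_size=4,
        )
    )
    def test_adjusted_factors_always_sum_to_zero(self, raw):
        averages = dict(zip((1, 2, 3, 4), raw))
        factors = adjust_seasonal_factors(averages)
        assert abs(sum(factors.adjusted_factors.values())) < 1e-9 * max(
            1.0, max(abs(v) for v in raw)
        )
        # matches the direct mean-subtraction oracle
        mean = sum(raw) / 4
        for q, v in zip((1, 2, 3, 4), raw):
            assert factors.adjusted_factors[q] == pytest.approx(v - mean, rel=1e-12, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            adjust_seasonal_factors({1: float("nan"), 2: 0.0, 3: 0.0, 4: 0.0})
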