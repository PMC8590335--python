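import numpy as np
import pytest
from hypothesis import settings

from survdecomp.datasets import load_plateau_age_strata, load_plateau_quarterly

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

# Published decomposition of the Plateau series: trend and seasonal
# variation for the 18 interior quarters (2013 Q2 .. 2017 Q3), at the
# table's 2-dp display precision.
PUBLISHED_TREND = [
    2284.00, 2196.00, 2500.33, 2171.67, 2920.67, 2824.67, 3012.00, 2588.33,
    3028.00, 3410.33, 3822.33, 3474.00, 3317.00, 3484.67, 3432.67, 3541.33,
    3480.00, 3760.00,
]
PUBLISHED_SV = [
    153.00, 780.00, -1325.33, 1178.33, -930.67, 597.33, 50.00, -36.33,
    -877.00, 970.67, -123.33, -87.00, 19.00, -256.67, 457.33, -361.33,
    74.00, -54.00,
]

# Published de-seasonalisation table: per-quarter SV totals, (n-1)-divisor
# averages, the mean correction, and the zero-sum adjusted factors.
PUBLISHED_Q_TOTALS = {1: 693.6667, 2: -1561.67, 3: 2037.33, 4: -941.33}
PUBLISHED_Q_AVERAGES = {1: 231.2222, 2: -390.417, 3: 509.3333, 4: -313.778}
PUBLISHED_CORRECTION = 9.090278
PUBLISHED_FACTORS = {1: 222.1319, 2: -399.507, 3: 500.2431, 4: -322.868}

PUBLISHED_ITLPQ = 86.82353

# Published three-year projection: (year, quarter, point, ci_low, ci_high)
# starting at the first quarter after the last trend-bearing one.
PUBLISHED_PROJECTION = [
    (2017, 4, 3524, 3408, 3640),
    (2018, 1, 4156, 4030, 4282),
    (2018, 2, 3621, 3503, 3739),
    (2018, 3, 4608, 4475, 4741),
    (2018, 4, 3871, 3749, 3993),
    (2019, 1, 4503, 4371, 4635),
    (2019, 2, 3968, 3845, 4091),
    (2019, 3, 4955, 4817, 5093),
    (2019, 4, 4219, 4092, 4346),
    (2020, 1, 4850, 4714, 4986),
    (2020, 2, 4316, 4187, 4445),
    (2020, 3, 5302, 5159, 5445),
    (2020, 4, 4566, 4434, 4698),
]
PUBLISHED_ANNUAL = {2018: 16256, 2019: 17645, 2020: 19034}

# Published age-specific case fatality table (percent, 2 dp).
PUBLISHED_CFR = {
    "<1 month": (5899, 31, 0.53, 0.34, 0.71),
    "1-11 months": (24983, 52, 0.21, 0.15, 0.26),
    "12-59 months": (30053, 49, 0.16, 0.12, 0.21),
}

PUBLISHED_YEARLY_CASES = {2013: 8027, 2014: 11824, 2015: 12783, 2016: 13841, 2017: 14460}


@pytest.fixture(scope="session")
def plateau_series():
    return load_plateau_quarterly()


@pytest.fixture(scope="session")
def plateau_strata():
    return load_plateau_age_strata()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def ma_oracle(counts, window=3):
    """Brute-force centered moving average: mean of every consecutive block."""
    half = window // 2
    out = []
    for i in range(half, len(counts) - half):
        block = counts[i - half : i + half + 1]
        out.append(sum(block) / window)
    return out


def decomposition_oracle(counts, quarters, divisor_mode="standard"):
    """Independent plain-loop decomposition: trend, SV, adjusted factors."""
    trend = ma_oracle(counts)
    sv = [counts[i + 1] - trend[i] for i in range(len(trend))]
    pools = {1: [], 2: [], 3: [], 4: []}
    for q, s in zip(quarters[1:-1], sv):
        pools[q].append(s)
    avgs = {}
    for q, vals in pools.items():
        div = len(vals) - 1 if divisor_mode == "paper" else len(vals)
        avgs[q] = sum(vals) / div
    corr = sum(avgs.values()) / 4
    return trend, sv, {q: avgs[q] - corr for q in (1, 2, 3, 4)}
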