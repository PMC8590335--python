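"""Decompose the packaged quarterly diarrhoea series into trend and seasonality.

Loads the 20 quarters of under-five diarrhoea counts (Plateau State,
2013-2017), computes the centered 3-quarter moving-average trend, the
seasonal variation SV_t = y_t - TR_t, and the zero-sum adjusted
quarterly seasonal factors.
"""

from survdecomp import (
    adjust_seasonal_factors,
    moving_average_trend,
    quarterly_seasonal_averages,
    seasonal_variation,
)
from survdecomp.datasets import load_plateau_quarterly
from survdecomp.decompose import decomposition_frame

series = load_plateau_quarterly()
trend = moving_average_trend(series, window=3)
sv = seasonal_variation(series, trend)

print(decomposition_frame(series, trend, sv).round(2).to_string(index=False))

factors = adjust_seasonal_factors(quarterly_seasonal_averages(sv, "paper"))
print("\nAdjusted seasonal factors (cases, zero-sum by construction):")
for q in (1, 2, 3, 4):
    print(f"  Q{q}: {factors.adjusted_factors[q]:+9.4f}")
print(f"  correction subtracted from each raw average: {factors.correction:.6f}")
# Positive Q1/Q3 factors mean those calendar quarters run above the trend
# line (the dry-season and late-rainy-season peaks); Q2/Q4 run below it.
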