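"""Generate synthetic surveillance series and test parameter recovery.

Simulates quarterly counts from the same additive model the
decomposition assumes (linear trend + zero-sum period-4 seasonality +
noise) and measures how well the pipeline recovers the known slope.
The seasonal run illustrates the method's one systematic limitation:
a 3-term moving average leaks period-4 seasonal signal into the trend,
biasing the slope estimate even without noise.
"""

import numpy as np

from survdecomp import SimulationConfig, generate_series, recover_parameters

pure = SimulationConfig(base_level=2300, slope=87.0, seasonal_factors=(0, 0, 0, 0),
                        noise_model="none", n_years=10)
report = recover_parameters(generate_series(pure))
print(f"noise-free pure line:   recovered slope {report.itlpq:.5f} "
      f"(error {report.slope_error:+.2e})")

seasonal = SimulationConfig(base_level=2300, slope=87.0, noise_model="none", n_years=10)
report = recover_parameters(generate_series(seasonal))
print(f"noise-free + seasonality: recovered slope {report.itlpq:.3f} "
      f"(leakage bias {report.slope_error:+.3f} cases/quarter)")

estimates = [
    recover_parameters(
        generate_series(SimulationConfig(base_level=2300, slope=87.0,
                                         noise_model="poisson", n_years=10, seed=s))
    ).itlpq
    for s in range(200)
]
mean, se = np.mean(estimates), np.std(estimates, ddof=1) / np.sqrt(len(estimates))
print(f"200 Poisson replicates:   mean slope {mean:.3f} +/- {se:.3f} SE")
# The replicate mean sits on the noise-free (leakage-biased) value, not
# on the truth of 87: Poisson noise adds variance but no further bias.
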