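# Methods

## Model

`survdecomp` analyses quarterly aggregate surveillance counts with the
classical additive decomposition

    y_t = TR_t + SV_t + i_t

where `y_t` is the observed case count in quarter `t`, `TR_t` the trend,
`SV_t` the seasonal component and `i_t` an irregular term taken as zero
for estimation. The pipeline has four stages.

**Trend.** `TR_t` is the centered moving average of an odd window of
consecutive counts (default window 3, i.e. `(y_{t-1}+y_t+y_{t+1})/3`).
The first and last `⌊window/2⌋` quarters carry no trend value. A window
of 3 follows the source analysis this package reproduces; note that a
3-term window does *not* annihilate period-4 seasonality (see
Limitations).

**Seasonal variation and factors.** `SV_t = y_t − TR_t` at every
trend-bearing quarter. The SV values are pooled by calendar quarter
(Q1 = Jan–Mar … Q4 = Oct–Dec) and averaged. Two divisor conventions are
offered:

* `standard` — divide each quarter's SV total by the number of values
  (the textbook seasonal-index convention);
* `paper` (default) — divide by (number of values − 1). This
  nonstandard divisor is what the reference analysis used; it is the
  default so that the packaged worked example reproduces the published
  tables cell for cell. Neither mode is endorsed as "correct"; they
  differ only in scaling of the raw averages.

The four averages are then mean-centered ("zero-sum adjustment"): the
correction is the mean of the four averages and is subtracted from each,
so the adjusted factors always sum to zero — a pure seasonal contrast
that cannot shift annual totals.

**Projection.** The trend slope is the *increase in trend line per
quarter* (ITLPQ): `(last TR − first TR)/(number of TR values − 1)`, a
two-point secant rather than a regression fit. Projected quarter `k`
beyond the last trend-bearing quarter gets trend `TR_last + k·ITLPQ`,
re-adds the adjusted factor of its calendar quarter, and is rounded
half-up to an integer case count (banker's rounding deliberately not
used; 4218.544 → 4219, x.5 → x+1). Negative point projections are
floored at 0 with a warning. The projection origin is the last
trend-bearing quarter, so the first projected row coincides with the
final observed (but trendless) quarter and doubles as an in-sample
sanity check.

**Confidence intervals.** The interval on a projected count `P` is
`round(P ± z·√P)` with `z` the two-sided normal quantile of the CI level
(`scipy.stats.norm.ppf`, 1.96 at 95%), computed from the *rounded*
point projection and floored at 0. This is a count-based
(Poisson-variance) normal approximation: treating the projected count as
a Poisson mean, its standard deviation is `√P`. The reference analysis
never states its interval formula; this rule was adopted because it
reproduces all 26 published bounds exactly, and it is documented here as
an explicit, auditable assumption rather than a derived property of the
projection model. It is *not* a prediction interval — it ignores
uncertainty in the slope and factors.

**Burden statistics.** The case fatality rate of a stratum with `d`
deaths among `n` cases is `100·d/n` percent. Its default interval is the
normal-approximation (Wald) binomial interval
`100·(p ± z·√(p(1−p)/n))`, clamped to [0, 100]; the exact
Clopper–Pearson interval is available (`method="exact"`) and is never
narrower. Both are delegated to
`statsmodels.stats.proportion.proportion_confint`. Wald is the default
because it matches the published CFR table at 2 dp; for very small `p·n`
the exact interval is the statistically safer choice. Case shares and
annual shares are plain percentages of the grand total at full
precision, with rounding left to the caller.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `window` | 3 | quarters | odd, ≥ 3; centered |
| `divisor_mode` | `paper` | — | `paper` = (n−1), `standard` = n |
| `horizon` | 13 | quarters | 1 in-sample + 12 future quarters |
| `ci_level` | 0.95 | fraction | normal quantile via scipy |
| `cfr_method` | `wald` | — | `exact` = Clopper–Pearson |

## Synthetic data

`generate_series` draws from exactly the generative form the
decomposition assumes: `count_t = max(0, round(base + slope·t +
factor[quarter(t)] + ε_t))` with ε either zero, Gaussian with fixed SD,
or replaced by a Poisson draw whose mean is the deterministic term
(floored at a tiny positive value so degenerate means stay drawable).
Noise is applied before integer rounding; the floor at 0 truncates the
noise distribution and slightly biases very low-count simulations
upward, which is irrelevant at surveillance scale (thousands of cases
per quarter). Defaults sit near the fitted values of the packaged
series — base ≈ 2300 cases, slope ≈ 87 cases/quarter, factors
(222, −400, 500, −322) — so synthetic series resemble the real one.
Generation is a pure function of the config including its seed
(`numpy.random.default_rng`).

What the simulator does **not** emulate: reporting delays and gaps,
outbreak bursts, over-dispersion beyond Poisson, multi-site structure,
or changing surveillance sensitivity. Passing recovery tests therefore
show the pipeline is a faithful implementation of the additive model —
not that real surveillance data satisfy that model.

## Numerical choices

* Internal arithmetic is double precision throughout; display rounding
  (2 dp for trend/SV, 4 dp for factors, integers for projections) is
  applied only at output.
* Golden-table tests compare at the published display precision:
  absolute tolerance 0.005 for 2 dp cells, 0.0005 for 3–4 dp cells.
* Zero-sum checks on adjusted factors use 1e-9 (relative to the input
  magnitude in property tests); `project` accepts factors whose sum is
  below 1e-6 in absolute value.
* Half-up integer rounding is `floor(x + 0.5)`, valid for the
  non-negative quantities it is applied to.
* Ties and degenerate inputs: paper divisor mode requires ≥ 2 SV values
  per calendar quarter (the (n−1) divisor would otherwise be zero);
  series shorter than the window, single trend values, and zero-case
  strata raise `InsufficientDataError`/`NoDataError` rather than
  returning NaNs.

## Known limitations

* **Seasonal leakage into the trend.** A 3-term moving average over
  period-4 seasonality leaves a periodic residue in `TR_t`. Because the
  ITLPQ is a two-point secant, the different seasonal mixes under the
  first and last trend points produce a deterministic slope offset —
  about −4.9 cases/quarter under the default simulation parameters —
  that no amount of noise averaging removes. Recovery tests therefore
  score seasonal configurations against an independent implementation
  of the same estimator (and against the noise-free estimator value for
  Monte-Carlo runs), not against the generating truth. A 2×4 centered
  moving average would remove the leakage but is out of scope: this
  package implements the reference method, not an improved one.
* The projection is a deterministic linear extrapolation; its intervals
  reflect only count-scale (Poisson) variability, not parameter or model
  uncertainty, and the constant-slope assumption is heroic beyond a few
  quarters.
* The packaged fixture's published companion figure quotes a trend-line
  slope of 0.02162 in unstated units; it cannot be reconciled with any
  obvious rescaling of the ITLPQ and is excluded from the reports this
  package produces.
* Only quarterly (period-4) seasonality is supported; the seasonal
  period is not yet a parameter.
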