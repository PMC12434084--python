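# Methods

This note documents the models, numerical choices and limitations behind
`exmort`, in the order the pipeline runs them.

## Data model

A mortality panel is a weeks × causes matrix of nonnegative counts with
week-ending dates at exact 7-day spacing.  Observed and simulated panels
hold integers; forecast panels hold reals.  Forecasts are deliberately *not*
rounded to integers: the downstream exceedance indicator uses a strict
`>` comparison, and rounding would create spurious ties (which count as
non-exceedance), biasing the forecast-window probabilities downward.  On
real-valued forecasts ties have measure zero, so the strict comparison is
clean.

## Synthetic panel generator

The generator emulates the structure of national weekly cause-of-death
tables: `K` correlated count series with trend and yearly seasonality.
For cause `k` at week `t` the expected count is

```
mu_k(t) = (baseline_k + trend_k * t) * (1 + A_k * sin(2*pi*(t - phase_k)/52.1775))
```

with the yearly period fixed at 365.25/7 = 52.1775 weeks.  Counts are
negative binomial (gamma-mixed Poisson) with dispersion `r` (variance
`mu + mu^2/r`; larger `r` is closer to Poisson) because real mortality
counts are overdispersed.  Cross-cause dependence enters through a Gaussian
copula on the latent uniforms, which preserves the configured marginals
exactly; the count-scale correlation is attenuated relative to the latent
correlation (by the normal-quantile transform and integer discreteness), so
it is validated empirically in tests rather than asserted exactly.

Defaults are chosen to resemble a 14-cause national weekly table over a
194-week window: baselines from ~700 (symptoms/ill-defined causes) to
~60,000 (all-cause) deaths per week, mild trends (0.5 deaths/week²),
10% yearly amplitude, dispersion 200 (a few percent extra-Poisson noise),
and an exchangeable latent correlation of 0.6, reflecting the strong
co-movement of cause-specific mortality series.  A within-week ("weekly")
seasonal cycle is not simulated and not fitted: the data are weekly
aggregates, so any such cycle is unidentifiable by construction.

What passing tests on synthetic data do **not** show: behaviour under
reporting delays (provisional-count back-fill), day-of-week artifacts,
structural breaks such as pandemic onsets, or cause-misclassification.  The
generator is stationary-seasonal by design.

All randomness flows from one explicit integer seed through
`numpy.random.default_rng`; no global state is touched, and identical
configurations reproduce bitwise-identical panels.

## Forecaster (phase I)

Per cause, ordinary least squares of counts on
`[1, t, sin(2*pi*j*t/P), cos(2*pi*j*t/P)]`, `j = 1..q` with `q = 10`
harmonic pairs and `P = 52.1775` weeks — the deterministic core of an
additive seasonal forecaster (linear trend, yearly Fourier seasonality, no
changepoints).  Fitting requires at least `2(2 + 2q)` weeks; a
rank-deficient design raises an error rather than silently pseudo-inverting.
An optional `log1p` scale fits `log(1+y)` and back-transforms, guaranteeing
nonnegative forecasts; on the identity scale forecasts are floored at zero.
Point forecasts only — the exceedance construction consumes no intervals.
The adapter protocol (`forecasting.Forecaster`) lets an external seasonal
forecaster be plugged into the pipeline; results downstream must not depend
on which is used.

In-sample observed-vs-fitted Pearson correlations are reported per cause;
a zero-variance series yields NaN with a warning rather than an error.

## Exceedance matrix and WCMI (phase II)

Combining a `T_obs`-week observed panel with a `T_fc`-week forecast requires
exact 7-day continuity and identical cause ordering.  The binary matrix has
one row per consecutive-week pair — `T - 1` rows for `T` weeks (194 + 104
weeks → 297 pairs); the indicator is 1 iff the later week strictly exceeds
the earlier.  Each row is dated by the *later* week of its pair.  Either
endpoint convention yields the same counts; only the row labels differ, so
the choice is presentational and documented rather than load-bearing.  The
single row comparing the last observed week to the first forecast week is
tagged `boundary`, and windowed estimates exclude it from both windows by
default (configurable), which gives 193 observed rows + 1 boundary + 103
forecast rows for the study-shaped 298-week panel.

Per cause, `ones` is the column sum and `p_hat = ones / n` at full
precision; a display helper rounds to 3 decimals.  The indicator sequence
is treated as i.i.d. Bernoulli within a cause — the binomial model is an
assumption of the method, not audited here (adjacent pairs share a week, so
the indicators are in truth 1-dependent).

The independence check uses the K×2 contingency table of
(exceedance, non-exceedance) counts per cause: Pearson chi-square without
continuity correction, df = K−1, and Cramer's V
`sqrt(chi2 / (N * min(K-1, 1)))` with `N = K*n` table total.  A zero margin
(every cause all-ones or all-zeros) is a degenerate-table error.

## Event probabilities (phase III)

Point, tail and interval events about one `Binomial(n, p)` count use exact
binomial computation.  Intervals (and the tail on the short side of the
mean) are accumulated from `exp(logpmf)` terms with compensated summation
(`math.fsum`): a far-tail interval computed as a cdf difference would
cancel catastrophically (two nearly equal cdf values), whereas summing pmf
terms keeps full relative precision at any depth.  Out-of-support bounds
clamp to the logically forced value (0 or 1) instead of erroring.

Joint probabilities are products of marginals (independence).  The
`two_dp_marginals` rounding mode rounds each marginal to 2 decimals before
multiplying; it exists to reproduce the display arithmetic used in
published tables and is off by default — rounding-then-multiplying is a
presentation artifact, not statistics.  Conditional probabilities equal the
target's marginal under independence; the conditioning event's probability
is still computed so a zero-probability condition raises an error.

Strict and non-strict inequalities are distinct event kinds with no silent
coercion, matching the mixed usage (`<`, `<=`, `>`, `>=`) that probability
queries arrive in.  The text grammar is `C1=141`, `C2<136`,
`138<=C7<=158`, with comma-joined terms forming joint events.

## Sums of non-identical binomials

**Exact route.**  Iterated pairwise convolution (`numpy.convolve`, direct —
not FFT, so no negative round-off mass) of the component pmfs over the full
support `0..sum(n_i)`, including the index-0 term of each overlap.  All
terms are nonnegative, so the relative error of each convolution sum is a
few ulps even for masses near 1e-300.  Event probabilities are taken from
pmf sums with `math.fsum` rather than the stored cumulative vector when a
tail is involved, for the same cancellation reason as above.  The default
support cap is 100,000; beyond it the exact route errors and points to the
saddlepoint method.

**Saddlepoint route.**  Built on the cumulant generating function
`K(s) = sum_i n_i log(1 - p_i + p_i e^s)`, evaluated via
`log1p(p_i * expm1(s))` for precision near `s = 0`.  The saddlepoint
equation `K'(s) = x` is solved by safeguarded Newton (bracketed, bisection
fallback, tolerance 1e-10 relative, ≤ 100 iterations; `K'` is strictly
increasing so the bracket always exists for `x` in the open support).

* Density: the lattice saddlepoint formula
  `exp(K(s) - s*t) / sqrt(2*pi*K''(s))` at `K'(s) = t`.
* Tails: the lattice Lugannani–Rice formula with second continuity
  correction — for `P(T >= t)` the saddle sits at the offset point
  `t - 1/2`, `w = sgn(s)*sqrt(2*(s*x - K(s)))`,
  `u = 2*sinh(s/2)*sqrt(K''(s))`, and
  `P = 1 - Phi(w) + phi(w)*(1/u - 1/w)`; for `P(T <= t)` the saddle sits at
  `t + 1/2` and the complementary form `Phi(w) - phi(w)*(1/u - 1/w)` is
  evaluated directly so the deep left tail keeps full relative precision.
* Near the mean (`|s| < 1e-5`), where `w` and `u` both vanish, the analytic
  limit `1/2 ∓ phi(0)*(s*sqrt(K'') + K'''/(3*K''^{3/2}))` replaces the raw
  formula (no division blow-up at integer-mean targets).
* Support edges: the first-order lattice density carries a Stirling-type
  relative error of roughly `1/(12m)` at `m` steps from a support edge
  (~8% at the very edge), which no tuning can remove.  Points within 4
  steps of either edge are therefore computed by truncated exact
  convolution (O(N·k²), exact), with the upper edge handled by reflecting
  `p -> 1-p`.  With this, the approximation's relative error against the
  exact oracle stays below ~2% over the entire support on heterogeneous
  component sets up to `sum(n_i) = 1000` (measured in the test suite with a
  5% assertion margin).
* Second-order density correction `1 + lambda4/8 - 5*lambda3^2/24` is
  available as `saddlepoint_pmf_order2`; the default stays first-order.

Degenerate components (`p` of exactly 0 or 1) are rejected by the
saddlepoint route — they shift the support deterministically and should be
removed by the caller; the exact route handles them fine.

Interval events under the saddlepoint method are computed as tail
differences taken on the side of the interval away from the mean, so a deep
tail interval is a difference of two same-scale small numbers, not of two
numbers near 1.

## Validation statistics

Per-cause `p_hat` on the observed window vs the forecast window, their
absolute differences, the Euclidean distance between the two vectors, and a
two-sample Wilcoxon rank-sum test.  The statistic uses the first-sample
Mann–Whitney convention (count of pairs with `x > y`, half per tie), with a
two-sided p-value from the tie-corrected normal approximation with
continuity correction; no exact-distribution branch is used at any sample
size (exhaustive enumeration exists in the tests as an oracle).  Applying a
two-*sample* test to what are structurally *paired* columns is reproduced
deliberately as the method defines it; a signed-rank test would be the
textbook alternative for paired data, and the discrepancy is noted here
rather than silently "fixed".

## Pipeline and determinism

The pipeline wires the stages behind a YAML configuration with one input
source (CSV path or simulation parameters), writes every artifact as CSV or
JSON, and records a manifest with the configuration hash, the seed and a
SHA-256 digest of each artifact.  Reruns with identical configuration are
byte-identical.  Stage failures abort with the stage name and a
machine-readable code; the CLI maps computation errors to exit code 1 and
usage errors to exit code 2.

## Problem sizes

The test suite and the acceptance script run at desk scale: binomial events
at `n = 297`; convolutions up to a few thousand support points; brute-force
enumeration oracles at ≤ 2^12 outcomes; 500–5000-replicate calibration
studies for estimator unbiasedness, chi-square null uniformity (1000
matrices) and Wilcoxon null rejection rate (5000 pairs of 14-point
samples); synthetic panels up to 5000 weeks for marginal/copula recovery.
These sizes make the whole suite run in well under a minute while leaving
the statistical assertions comfortably powered.

## Known limitations

* The binomial model ignores the 1-dependence of adjacent indicators and
  any seasonality in exceedance probability; it inherits these assumptions
  from the method it implements.
* The forecaster has no changepoints, so a structural break in the training
  window bleeds into the trend estimate.
* The generator's copula correlation is specified on the latent scale, not
  the count scale; users targeting an exact count-scale correlation must
  calibrate the latent value.
* Joint probabilities assume independence across causes even though the
  underlying count series are correlated; the chi-square check tests
  homogeneity of exceedance frequency, which is necessary but not
  sufficient for independence.
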