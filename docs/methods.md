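# Methods

## Standardization chain

A tube's relative leakage is R_T = L_T / L_K with L_K the same tube's
conductivity after the maximal-damage control. The index of injury
I_T = 100 (R_T − R_o)/(1 − R_o) zeroes handling damage; the adjusted index
I_adj = 100 (R_T − R_o)/(R_max − R_o) additionally treats the genotype's
low-temperature leakage plateau as 100 % damage. The identity
I_adj = 100 I / I_max with I_max = 100 (R_max − R_o)/(1 − R_o) holds exactly
(asserted to 1e-12 relative in the tests).

Per-genotype aggregation choices (both configurable):

* **Baseline R_o** — default: mean R over unfrozen tubes (temperature > 0 °C).
  The replicate mean is the least-variance choice when replicate controls
  exist. Alternative `min_of_4C_or_minus5C`: minimum R over tubes warmer than
  −7.5 °C, for single-tube designs where a minimum is the only defensible low
  estimate of handling leakage (the −7.5 °C cut accommodates actual chamber
  temperatures running ~1.5 °C below a −5 °C target).
* **Maximum R_max** — default: maximum over per-temperature replicate means,
  robust to one leaky tube. Alternative `max_replicate`: the literal maximum
  single measurement; it is systematically higher under noise.

Values of R > 1 and negative injury indices are flagged and retained.
Clamping to [0, 100] exists behind an explicit flag only: clamping before
fitting censors the residual distribution near the asymptotes and biases c
and d estimates.

## Curve fitting

All fits are unweighted least squares on replicate-level points (temperature
means would discard within-temperature variance and overweight sparse
temperatures). The log-logistic v(T) = c + (d−c)/(1+e^{b(T−u)}) is fit under
the mode's constraints with `scipy.optimize.least_squares` (TRF, bounds):

* bounds: c ≥ 0; d ≤ 110 by default (soft headroom above 100 so slightly
  leaky data do not stick on the boundary; configurable); 0 < b ≤ 10 /°C
  (a transition sharper than 10 /°C is a step, not a damage curve — the cap
  exists because step-like quartile visual-damage data otherwise push b to
  infinity without improving the fit).
* start values are deterministic and derivative-free: c0/d0 from the min/max
  per-temperature means, u0 where the interpolated mean response crosses its
  mid-range, b0 = 4/temperature-span (the logistic's mid-slope relation),
  with two fallback starts at b0/4 and 4·b0; the best SSE wins. On
  noise-free logistic data the solver reproduces (u, b) to ~1e-9.
* degenerate inputs (fewer than 4 distinct temperatures, fewer points than
  free parameters + 1, or per-temperature means spanning < 1e-6) raise a
  typed error; solver failure returns a fit flagged `converged=False`, and
  critical-value tables omit such genotypes with a warning.

The Gompertz curve is fit in (log b, k) with k ∈ [−10, −1e-9]; the log-b
parametrization keeps the doubly-exponential model conditioned across the
realistic b range (1e-4 … 1e4). LT_max = ln(b)/k equals the temperature of
maximum |dI/dT| (verified numerically against a fine grid) and is warmer
than LT50 whenever k < 0.

Critical temperatures use the relative-damage convention: LT_p solves
(v − c)/(d − c) = p/100, so LT_p = u + ln((100−p)/p)/b and LT50 = u for every
logistic mode, regardless of the asymptotes. An absolute-threshold variant
(`absolute=True`) is provided and returns NaN with a warning when the
threshold lies outside the fitted span — with an autoclave control the raw
leakage of hardy tissue often never reaches absolute 50 %, which is precisely
the argument for the relative convention. Species-level fits pool replicate
points across genotypes rather than averaging genotype parameters.

## Control calibration

The zero-intercept Deming slope minimizes Σ(y − s·x)²/(δ + s²); the
stationarity condition is the quadratic Sxy·s² − (Syy − δ·Sxx)·s − δ·Sxy = 0,
whose positive root is used in closed form. δ defaults to 1 (equal error
variances: both axes are read by the same conductivity probe). With δ = 1 the
fit is orthogonal regression through the origin and satisfies
slope(y~x)·slope(x~y) = 1 exactly; exact scale equivariance under y → a·y
requires δ → a²·δ (with δ held fixed it is only approximate — a property of
Deming regression, not of this implementation).

Outlier screening (optional, on by default): perpendicular residuals from an
initial all-data fit, flag |r − median| > 3 × 1.4826 × MAD, remove once,
refit. Single-pass by design — iterating the rule can cascade on
heteroscedastic conductivity data, where residual spread grows with tube
size. The 95 % CI is a seeded nonparametric bootstrap over pairs (10 000
resamples by default).

Conversion to the liquid-nitrogen standard divides R by the slope and caps at
1.0 (relative leakage above its own control is physically meaningless; capped
points are counted in a warning, and the cap can be disabled for algebraic
work). The adjusted index is invariant under conversion — the scale factor
cancels between numerator and denominator — so I_adj is always computed from
the original records.

## Validation metrics

Bias is mean(pred − obs) with the leakage-derived quantity first, so positive
bias means leakage reads warmer/larger than the reference. Fitted-approach
comparisons evaluate fitted curves on a 1 °C grid spanning the tested range,
not raw points; restricted-range statistics condition on the reference
(second) curve's value, and a 15-percentage-point band fraction summarizes
agreement with the 1:1 line. The LT-threshold grid compares LT at p% leakage
with LT at q% visual damage across genotypes for p, q ∈ {10, …, 90} and emits
boolean masks at the conventional cutoffs (ρ > 0.55, |bias| < 5 °C,
RMSE < 7 °C). Correlations default to Pearson (Spearman behind a flag); cells
with fewer than 3 aligned pairs are undefined.

The lowest survival temperature is applied literally, per temperature
independently, with no monotonicity repair: LST = the coldest tested
temperature at which no segment exceeds 50 % damage. If the warmest freezing
temperature already has a failing segment the statistic is undefined (the
tissue was dead on arrival; colder temperatures passing would be noise).

## DTA exotherm detection

The trace is smoothed with a 0.5 °C moving average, a running median over a
5 °C window forms the baseline (robust to sub-°C exotherm pulses), and peaks
are called on the baseline-subtracted signal with
`scipy.signal.find_peaks`. The prominence floor is k × 1.4826 × MAD of the
**raw** residual (default k = 6): an exotherm must stand out against the
instrument noise amplitude, not merely against the smoothed trace — with the
floor referenced to smoothed noise, extreme-value statistics over a
multi-thousand-sample trace produce spurious calls. Peaks warmer than −15 °C
are classed HTE (benign extracellular ice; configurable cutoff since the
boundary is conventional), colder ones LTE. The species summary averages each
genotype's most prominent LTE; genotypes without one are excluded with a
warning. The pipeline operates in the sample domain and is invariant to
additive voltage offsets and uniform time rescaling.

## Synthetic data generator

The generator emulates a multi-species campaign at the standard design
(12 species × 3 genotypes × 3 replicates × {4, −10, −20, −30, −40, −60,
−80} °C) with a latent logistic damage fraction D(T) per genotype and

    L_T = P (f0 + (m − f0) D(T)) (1 + ε),   ε ~ N(0, sd)
    L_K = P (1 + ε)            (autoclave)   or   P·m (1 + ε)   (liquid N)

Defaults and why: pool P = 150 µS/cm (the scale of a low-concentration
conductivity probe's range after dilution); handling fraction f0 = 0.10;
maximum freezing-induced fraction m = 0.58 (woody maple twigs leak just over
half their heat-extractable electrolytes even in liquid nitrogen); noise
sd = 0.03, multiplicative because conductivity errors scale with magnitude —
larger, leakier samples scatter more. Species LT50s are drawn uniformly on
(−28, −12) °C with ±1.5 °C genotype jitter, slopes on (0.15, 0.40) /°C —
the ranges a late-winter temperate hardwood panel spans. Visual damage comes
from a distinct curve shifted −3 °C and steepened 1.5×, then snapped to the
quartile scale (ties toward 50), so EL-vs-VD grids have genuinely different
curves to compare. Control-pair simulation adds a uniform tube-size factor
(0.5–1.5×) so both axes carry real spread. DTA traces follow the −4 °C/hour
protocol ramp with Gaussian heat pulses (sd 0.3 °C, amplitude 8× noise) and a
small linear drift to exercise baseline subtraction.

What the generator does **not** emulate: temperature-dependent variance
structure beyond the multiplicative term, replicate-tube correlations,
non-sigmoid (multi-phase) damage accumulation, HTE multiplicity from pooled
segments, or the empirical gap between −80 °C freezing and true
liquid-nitrogen leakage (its plateau and the LN control coincide at m by
construction). Passing recovery tests therefore demonstrate correctness of
the estimation chain under the stated noise model, not robustness to every
pathology of field data.

## Known estimator properties and limitations

* **Plateau-normalization bias.** The Lim route estimates R_max as a maximum
  over noisy plateau means; the estimate is upward-biased, which deflates
  I_adj and pulls the fitted LT50 cold by ≈ 0.2–0.4 °C at the default noise
  level, on top of a small structural term (≈ 0.1 °C) that exists even
  noise-free whenever baseline damage at 4 °C is non-negligible (warm,
  shallow-sloped genotypes). The free-asymptote (Anderson-mode) fit on R has
  no such bias — its asymptotes absorb the affine map — and is the estimator
  of choice when the latent inflection itself is the target. Mean absolute
  LT50 error at default conditions is ≈ 0.3 °C (free-asymptote) and
  ≈ 0.5 °C (Lim route), both measured by the recovery tests.
* Confidence intervals for LT_p are not provided (the Deming slope CI is the
  only interval estimate); Richards-family and Bayesian fits are out of
  scope.
* The HTE/LTE boundary and the detector's windows are conventions, not fitted
  quantities; traces whose cooling span is under 10 °C are rejected rather
  than guessed at.
* Problem sizes in the test suite (≈ 200 genotypes for recovery, 100 seeds
  for slope recovery, 50 traces for the detection benchmark) are the
  package's chosen benchmark sizes; all complete in well under a minute
  each.
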