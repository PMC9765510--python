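# Methods

## The measurement and its model

`svquench` quantifies how strongly a dissolved sample — a filtered bacterial
culture supernatant or a pure chemical — quenches a phosphorescent O₂-sensing
dye. The experiment is a 96-well serial-dilution assay: the sample is 2-fold
serially diluted (typically 5 steps, i.e. six concentrations from neat down to
1/32), each well is read on a plate reader **before** sensor addition (the
"pre" phase: media background plus any intrinsic sample fluorescence) and
**after** ("post"). Media-only blank wells and sensor-in-buffer control wells
accompany every plate.

Quenching follows the linear Stern-Volmer relation

    I₀ / I = 1 + K_SV · [Q]

with I₀ the unquenched sensor intensity, I the sensor intensity at quencher
concentration [Q], and K_SV the Stern-Volmer constant. For pure chemicals
[Q] is molar and K_SV has units M⁻¹; for supernatants of unknown composition
[Q] is a relative concentration in (fold dilutions)⁻¹ — neat supernatant = 1 —
and the slope is an *effective* constant K̃_SV. Every concentration-bearing
quantity carries an explicit unit tag and the two systems cannot be mixed in
one fit. The model is strictly linear (purely dynamic quenching at this
fidelity); downward-curving plots, static/dynamic discrimination and
conversion of quenching to apparent [O₂] are out of scope.

## From raw readings to Stern-Volmer points

Adding sensor stock (v_add, default 11 µL) to a well of volume v₀ (default
100 µL), then withdrawing an equal volume, dilutes everything already present
by

    f = v₀ / (v₀ + v_add)        (100/111 ≈ 0.9 by default).

The pipeline computes, per sample well,

    I = (post − blank_post) − f · (pre − blank_pre),
    [Q] = f · [Q_pre],

blank-correcting each phase separately before the f-rescaled subtraction —
the only order in which media autofluorescence cancels exactly. The
subtraction also cancels the sample's intrinsic fluorescence exactly for any
fluorescence-vs-concentration slope (a tested invariant). Wells with I ≤ 0
(strongly absorbing/fluorescent samples) are excluded with a recorded reason
rather than clipped, which would bias I₀/I upward.

I₀ is the blank-corrected mean of the sensor-only control wells. The ratio
variance uses first-order (delta-method) propagation,

    var(I₀/I) = (I₀/I)² · (var_I₀/I₀² + var_I/I²),

which Monte-Carlo tests confirm to within 10% whenever all coefficients of
variation are ≤ 5%.

### Variance estimation and weighting

Plate-reader noise is proportional to signal, so the relative replicate
spread is a property of the instrument, not of any single concentration.
Reading variances are therefore estimated from the **pooled squared
coefficient of variation** across all replicated well groups of the series
(each concentration per phase), applied as var = cv²·(local mean signal)².
With only 2×2 replicate wells per concentration, per-concentration variance
estimates carry 1–3 degrees of freedom and make 1/variance weights chase the
very fluctuations being fitted; pooling restores well-calibrated confidence
intervals. The blank-mean variance is added on top (this contribution can be
switched off in `PreprocessConfig`).

Each fitted point's `var_y` is the full delta-method variance above, but its
**weight** is the reciprocal of the replicate-noise component only. The I₀
contribution is identical for every point on a plate — an error in the I₀
estimate rescales all ratios in unison, moves the fitted slope, and never
appears in residuals — so it is propagated separately at the slope level (see
below). The variance of the I₀ estimate itself is likewise built from the
plate-wide pooled cv rather than the spread of the handful of control wells,
whose 3 degrees of freedom would make the slope's standard error itself
unacceptably noisy.

## The slope-only weighted fit

The Stern-Volmer intercept is theoretically 1 and is not fitted: the
regression is (I₀/I − 1) = k·[Q] through the origin, by weighted least
squares (statsmodels WLS), pooling all biological and technical replicates
into one fit without aggregation. The closed-form estimate is
k̂ = Σ wᵢqᵢ(yᵢ−1) / Σ wᵢqᵢ², verified in tests against an independent
brute-force grid minimizer of the weighted SSE.

The standard error combines two terms:

1. the residual-rescaled WLS covariance (point-independent noise), and
2. a common-mode term for the shared I₀ uncertainty,
   (∂k̂/∂I₀)²·var(Î₀) with ∂k̂/∂I₀ = (Σ wqy / Σ wq²)/I₀.

The symmetric confidence interval is k̂ ± t₀.₉₇₅,ₙ₋₁ · se. On the reference
simulation (below) this yields empirical 95% CI coverage of 0.95–0.97 for
K ∈ {0.25, 1, 4} and median relative bias within ±2.5%; omitting the
common-mode term drops coverage to ≈0.6, which is why it is part of the
estimator.

### Inner-filter exclusion

Strongly light-absorbing (intrinsically fluorescent) quenchers such as
pyocyanin attenuate excitation/emission at high concentration, mimicking
quenching. For such quenchers the highest `inner_filter_drop` (default 1)
distinct concentrations are excluded before fitting. A quencher counts as
fluorescent when flagged explicitly, or — when the flag is unset — when its
pre-addition fluorescence correlates with concentration at Pearson R ≥ 0.9;
an explicit flag always wins over auto-detection. The same pre-addition
correlation doubles as a dilution QC statistic.

### Non-quencher classification

A sample is called a non-quencher when either

- Pearson R of I₀/I vs [Q] over the included points (computed after
  inner-filter exclusion) is below 0.4 or not computable, or
- the projected fractional quenching at a reference concentration,
  1 − (1 + k̂·q_ref)⁻¹ with q_ref = 1 in the data's unit (neat supernatant,
  or 1 M for chemicals), does not exceed 2 × the unquenched sensor's
  coefficient of variation (a ≈95% variability envelope; the multiplier is
  configurable since "overlap with sensor variability" admits more than one
  quantification).

A negative fitted slope projects zero quenching and is always a
non-quencher. Non-quenchers keep their fitted slope and CI in the output
table. On simulated plates, K = 0 plates are called non-quencher in ≥ 99% of
runs and K = 1 plates at 3% noise are called quencher in ≈100%.

## Lifetime module

Dynamic quenching shortens the excited-state lifetime in the same proportion
as intensity, τ₀/τ = 1 + K_SV[Q]. Decay traces are fit to a mono-exponential
with additive offset, I(t) = A·exp(−t/τ) + B (scipy `curve_fit`, initialized
by log-linear regression on baseline-subtracted early samples); the sensors
modeled are single-lifetime emitters at this fidelity and bi-exponential
fitting is out of scope. A titration series of fitted lifetimes goes through
the same slope-only weighted regression, with each point weighted by its own
lifetime-fit variance and the shared τ₀ uncertainty propagated as a
common-mode term exactly as for I₀. Cuvette titrations account for volume
growth: after additions totalling v_add of stock concentration c, the
concentration is c·v_add/(v₀+v_add).

## The synthetic-data generator

`simulate_plate` emulates the assay's statistical structure and is the ground
truth for end-to-end validation:

    pre  = blank + g·q_pre                                   (× (1 + ε))
    post = blank + f·g·q_pre + I₀/(1 + K·f·q_pre)            (× (1 + ε))

with g the intrinsic-fluorescence slope and ε ~ Normal(0, noise_fraction)
independent per reading. Defaults are the study conditions: a 6-concentration
2-fold series (1 … 1/32 fold-dilutions), biological × technical duplicates,
3% multiplicative noise, f = 100/111, plus 4 blank and 4 sensor-only control
wells. Values the protocol does not pin down were set once to realistic
plate-reader magnitudes: I₀ = 10 000 a.u., blank = 100 a.u. Noise is
multiplicative because read noise scales with signal and blanks stay
low-noise (an additive mode exists for sensitivity checks). An optional
exponential inner-filter attenuation of the sensor component exercises the
exclusion rule, and `v_added = 1` with no withdrawal reproduces the early
protocol variant (f = 100/101).

What the generator does **not** emulate — and hence what passing tests do not
demonstrate about real plates: drift between the pre and post reads, spatial
(edge/gradient) well effects, pipetting errors that violate the exact 2-fold
design, sensor photobleaching, chemical reactions between quencher and
sensor, and detector saturation. The dual-dye reference channel of
encapsulated nanosensors is not simulated; fits use sensing-channel
intensities only.

## Numerical choices and degenerate inputs

- Noiseless data give zero variances; all weights then fall back to a common
  constant so the fit remains defined and exact (recovering the generating K
  to ~1e-12 for any g and any f).
- All concentrations identical → rank-deficiency error; fewer than 3 included
  points → insufficient-points error; every point excluded → empty-series
  error; sensor signal not exceeding blank → invalid-baseline error.
- Pearson R returns NaN (flagged "not computable") on zero-variance axes and
  then forces a non-quencher call.
- Replicated q values are kept as separate fit points; no tie-breaking or
  aggregation is applied.
- Pre-phase-free plates (non-fluorescent pure chemicals) can be encoded by
  setting pre readings equal to blanks.

## Problem sizes used in validation

The test suite and the acceptance script run entirely on synthetic data:
per-seed plates of 24 sample wells; 20–25 seeds for CI-calibration checks;
500 seeds per K ∈ {0.25, 1, 4} for bias/coverage; 200 seeds for
classification rates and lifetime recovery. These sizes give binomial
standard errors of ~1% on coverage estimates while the full suite completes
in well under a minute.

## Known limitations

- The linear model is assumed, never tested against curvature; a real sample
  with combined static + dynamic quenching will be summarized by a single
  effective slope.
- The common-mode error propagation is first-order; at coefficients of
  variation well above ~10% the delta method degrades.
- Classification thresholds (R < 0.4, 2×cv envelope, 1-concentration
  inner-filter drop) are field conventions exposed in `FitConfig`, not
  quantities the package can derive from data.
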