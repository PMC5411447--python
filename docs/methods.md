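# Methods

## The allometric model

Each crop's per-stalk aboveground dry mass is modelled as a power law

    Y = a · X^b + ε,

with `Y` in g, `X` the basal stalk diameter `D` (cm, at the 20 cm cut
point) or the dewlap height `H` (cm), `a > 0` in g (the predicted mass of
a unit-dimension stalk), and `b` dimensionless. The error `ε` is additive
on the mass scale: log transformation does not stabilize the error
variance for these destructive harvest data, so the model is fitted by
untransformed nonlinear least squares rather than back-transformed log-log
OLS. The log-log OLS estimate is used only to start the nonlinear solver
(and is exposed via `fit_loglog` for comparison). The solver is a
trust-region least-squares iteration with convergence declared when the
relative reduction in SSR falls below 1e-10; non-convergence raises an
error carrying the best iterate and its gradient norm.

Because height, diameter, and their product all track stalk size, the
candidate set also includes three fixed-coefficient generalized equations
published for tropical woody and shrub biomass, and a combined `D·H`
power fit is available (`Predictor.D_TIMES_H`) although it is not in the
default candidate set — combining the two predictors does not improve on
`D` alone for these grasses.

## Goodness of fit and ranking

For a model with `k` parameters evaluated on `n` stalks:

- R² = 1 − SSR/SST_c with SST_c the corrected total sum of squares;
- RMS = SSR/(n − k);
- AIC = n·ln(SSR/n) + 2(k + 1) — the least-squares form, counting the
  error variance as a parameter; constant offsets cancel across candidates
  so rankings are unaffected by the convention;
- AICc = AIC + 2(k + 1)(k + 2)/(n − k − 2);
- p from the regression F statistic [(SST_c − SSR)/(k − 1)]/[SSR/(n − k)]
  on (k − 1, n − k) degrees of freedom.

Fixed-coefficient generalized models are scored with k = 2: the published
power forms have two parameters even though they are not re-estimated
here, and k = 2 keeps the F-test degrees of freedom well defined. A
perfect fit (SSR = 0) reports AIC = −inf with a warning rather than
failing.

`rank_models` sorts by descending R²; candidates within 0.005 of a
cluster's best R² (the resolution of a two-decimal report) are ordered by
ascending AICc, then RMS, with the input order as the final stable
tie-break. The threshold is configurable.

The registry fixture carries the published goodness-of-fit indices of all
fifteen models purely for reference and ranking demonstrations; the exact
software conventions behind the published AIC values are unknown, so those
numbers are never recomputed or asserted.

## Validation statistics

With `P` predicted and `O` observed at independent sites, and `P̂` the OLS
fit of `P` on `O` (predicted regressed on observed, so systematic error is
the displacement of that line from the 1:1 line):

- MSE = (1/n)Σ(Pᵢ − Oᵢ)²,
  MSE_s = (1/n)Σ(P̂ᵢ − Oᵢ)²,
  MSE_u = (1/n)Σ(Pᵢ − P̂ᵢ)²; MSE = MSE_s + MSE_u is an algebraic identity
  of OLS, which requires the population (divide-by-n) form;
- Willmott's index of agreement (squared-difference form)
  d = 1 − Σ(Pᵢ−Oᵢ)² / Σ(|Pᵢ−Ō| + |Oᵢ−Ō|)², in [0, 1] by the triangle
  inequality;
- Nash–Sutcliffe model efficiency EF = 1 − Σ(Pᵢ−Oᵢ)²/Σ(Oᵢ−Ō)².

Numerical care: `P̂` is computed in centered form
`P̄ + slope·(O − Ō)` to avoid cancellation, and observations whose spread
is within 1e-10 of their magnitude are rejected as zero-variance since the
regression is then numerically meaningless. The value of d is clamped to
[0, 1] against last-ulp rounding.

## Site calibration and the rainfall modifier

"Near 1 slope and near 0 intercept" is formalized as minimizing

    J = (slope − 1)² + (intercept/Ō)²,

the intercept scaled by mean observed mass so the two terms are
commensurate (equal weights; configurable in principle). For the exponent,
J(b) can be mildly non-convex, so a 64-point grid scan over the supplied
bounds (default [0.1, 2.0]) brackets the optimum and golden-section search
refines it to 1e-6, warning if the optimum sits at a boundary. For the
coefficient, both slope and intercept are linear in `a`, so J(a) is
quadratic with the closed-form minimizer `a* = m/(m² + q²)` (m, q the
slope and scaled intercept of the unit-coefficient predictions); the
closed form is cross-checked against the search at call time.

Calibrated exponents from ≥ 3 sites are regressed on each of the five
weather covariates separately — four sites cannot support multivariate
selection — and the covariate with the highest R² is selected, ties
resolved in favor of rainfall. Exponent calibration is preferred over
coefficient calibration for modifier fitting, as it meets the 1:1
objective better. The adjusted predictor is
`Y = a·D^{c0 + c1·rain}`; an adjusted exponent outside [0, 3] triggers a
warning but the value is still returned, since the caller may be probing
extrapolation.

## Synthetic harvest generator

The generator emulates what the analysis assumes about destructive
harvests, not crop physiology:

- `D ~ lognormal(ln 2.0, 0.5)` cm. No distributional information about
  observed diameters exists, so this is a modelling choice: a 2 cm median
  is typical of these grasses, and σ = 0.5 makes the development fit at
  the default noise level reach R² ≈ 0.97–0.98, the fit quality these
  site-specific calibrations report (cv² ≈ (1 − R²)·var(ln Y) with
  var(ln Y) ≈ (b·σ)²).
- `H = 26.6·D^1.94` cm with 3 % multiplicative jitter. The pair (c, d) is
  obtained by composing the published napiergrass D and H models
  (b_H = b_D/d and a_H = a_D·c^(−b_D/d)), giving ≈ 1 m stalks at
  D = 2 cm and H-model exponents of realistic magnitude.
- `Y = a·D^{b(rain)} + ε` with `b(rain) = b0 + s·(rain − rain_ref)`,
  s = 2e-4 mm⁻¹ by default. Per-crop (a, b0) equal the published
  site-specific models (151.26/0.68, 144.99/0.72, 309.34/0.71), and
  `rain_ref` is the development-period rainfall at the development site
  (21.1/157.2/236.2 mm), so development data carry the baseline exponent
  and the four validation sites carry rainfall-shifted exponents — the
  structure the calibration stage is designed to recover.
- Noise is additive with constant CV 5 % of the mean (heteroscedastic, as
  destructive biomass data are); a constant-SD option exists. Negative
  draws are rejected and redrawn rather than truncated, avoiding a point
  mass at zero; redraw counts are logged.
- Determinism: one RNG substream per site, keyed by a CRC32 hash of
  (crop, site) combined with the seed, so adding a site never changes
  another site's draws and identical configs give byte-identical output
  files.

What the generator does **not** emulate: replicate-level (block) effects,
within-site spatial structure, measurement error in D and H, crop
phenology, or any mechanistic rainfall–growth pathway. Passing tests
therefore demonstrate that the pipeline recovers the assumed structure
when it is present, not that real stands obey it.

## Problem sizes and defaults

The study designs are used as-is: 30 development stalks (10 × 3) and 300
validation stalks (25 × 3 × 4) per crop. Recovery and improvement
properties are checked over 20–50 seeds at these sizes; the residual-CV
check uses n = 1200. The full three-crop pipeline runs in a few seconds
on one CPU.

## Known limitations

- Units (cm, cm, g) are a convention chosen so the published coefficients
  produce plausible per-stalk masses; the source equations state no units.
- Per-area yield scale-up (stalks per unit area) is out of scope.
- Predictions are point estimates; no uncertainty intervals are produced.
- The b–rainfall relation is assumed linear — the simplest form consistent
  with regressing calibrated values on a covariate — and is fitted from
  only four sites; extrapolating it far outside the observed rainfall
  range is not advised (hence the [0, 3] exponent sanity warning).
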