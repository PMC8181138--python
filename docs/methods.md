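# Methods

## Model

Rib cortical bone failure strain in tension is treated as a positive random
variable `T` (true, i.e. logarithmic, strain) following an accelerated
failure time (AFT) model

    ln(T) = β₀ + β₁·AGE + σ·ε,

with `ε` standard normal (log-normal family), standard logistic
(log-logistic), or standard Gumbel-minimum (Weibull; shape α = 1/σ).
Fracture risk at strain `s` and age `a` is `P(T ≤ s)`, the failure-strain
CDF. The AFT structure makes aging a pure rescaling of strain: the
acceleration factor `exp(β₁·Δa)` multiplies the strain required for equal
risk, so with the reference log-normal β₁ = −0.0130 a decade of aging
reduces it to 87.8% (a 12.2% reduction).

All evaluation is on **true strain**, the convention of explicit FE codes;
engineering strains are converted on ingest via `ln(1+e)` and the original
convention is recorded. Strict mode rejects non-positive strains; lenient
mode (used for per-rib aggregation, where a mesh can legitimately report
zero strain) maps them to risk 0 with a logged warning. Ages outside the
fitted span 17–99 years produce a logged extrapolation warning, not an
error. The reference parameter sets are shipped exactly at their published
4-decimal precision.

## Fitting pipeline

The risk-curve construction follows the standard ISO-style 12-step
procedure for injury risk curves from PMHS data:

- **Covariate screen.** Type-II ANOVA (statsmodels) of `ln(failure strain)`
  on age, sex, and their interaction at α = 0.05. Type II is the
  conventional default for unbalanced data. Single-sex data drop the sex
  terms with a warning; a zero-variance predictor is reported as not
  estimable rather than producing a meaningless F from a rank-deficient
  design.
- **Maximum likelihood.** Quasi-Newton (BFGS) on (β, ln σ) —
  unconstrained via the log transform of the scale — with gradient
  tolerance 1e-8, started from the OLS fit of `ln(strain)` on the
  covariates with the residual SD as initial σ; a Nelder–Mead polish runs
  only if BFGS reports failure. The likelihood uses density terms for
  exact observations (including the 1/t Jacobian, so log-likelihoods and
  AICs are directly comparable with flexsurv/lifelines conventions) and
  survival/CDF terms for right-, left-, and interval-censored rows.
  Censoring support exists for generality; the reference study's data are
  all exact. A scale collapsing toward zero raises a boundary error. The
  test suite cross-checks all three families against lifelines' AFT
  fitters on identical data (agreement ~1e-4 in log-likelihood).
- **Covariance.** Observed information: a central-difference numerical
  Hessian at the optimum, inverted and symmetrized. This feeds Wald
  intervals and the delta-method bands (the "asymptotic normal" machinery).
- **Influence.** DFBETAs by exact leave-one-out refits — n refits cost
  well under a second at coupon sample sizes and avoid one-step
  approximation ambiguity. Entry (i, j) is the standardized change
  `(θ̂ⱼ − θ̂ⱼ⁽⁻ⁱ⁾)/SE(θ̂ⱼ)`; an observation is flagged when any entry
  exceeds 2/√n. A failed leave-one-out refit marks the row unevaluable
  instead of aborting.
- **Residual checks.** Standardized residuals `(ln s − xβ)/σ` against the
  family's error quantiles at plotting positions `(i−0.5)/n`, plus
  residual-vs-fitted (Tukey-Anscombe) pairs.
- **Selection.** AIC = 2k − 2·loglik; comparison refuses fits on different
  data or covariate sets (a data fingerprint travels with each fit). Equal
  AICs break by the fixed preference order log-normal, log-logistic,
  Weibull, logged.
- **Confidence bands.** Delta method on the linear-predictor scale
  `z = (ln s − xβ)/σ`, where the estimator is asymptotically normal, then
  mapped through the family CDF. This keeps bands inside [0, 1] and
  containing the point estimate; whether the original analysis propagated
  on the risk scale instead is not documented, and the linear-predictor
  choice is this package's decision for boundedness.
- **Quality indices.** At each (risk level ∈ {5, 25, 50%}, age ∈ {25, 50,
  75}) cell, the relative 95% band width `(upper − lower)/mid` at the
  strain giving that risk, graded good (<0.5), fair (<1.0), marginal
  (<1.5), unacceptable otherwise — the WorldSID-style convention; the
  boundaries are configurable because the underlying formula is a
  convention, not a property of the data. Note that at the 5% level the
  small denominator inflates the relative width, so low-risk cells grade
  harsher than mid-risk cells for the same absolute band.

## Probabilistic framework

Per-rib fracture indicators are assumed independent Bernoulli variables
with probabilities from the risk function at the occupant's age — the same
assumption as the original framework; rib-to-rib correlation is a known
limitation, not modelled. The number of fractured ribs then follows the
Poisson-binomial distribution, computed exactly by the O(n²) iterative
convolution recurrence (numerically stable at n = 24; validated against
exhaustive 2ⁿ enumeration). NFRk+ risks are tail sums. Each rib
contributes one peak first principal strain, extracted upstream; sternum
and costal cartilage are not counted.

Population risk curves are binomial-family GLMs with logit link on the
fractional NFR2+ responses over delta-v and age (statsmodels IRLS);
dispersion is estimated from Pearson residuals in quasi-binomial style but
does not move the coefficients. Constant responses yield an intercept-only
curve with a warning; separation is flagged as non-convergence. The
50%-risk severity is the closed-form logit inversion
`Δv₅₀ = (logit(r) − b₀ − b_age·a)/b_Δv`.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes,
not the physics behind it:

- **Coupons.** n = 58 donors; ages truncated-normal(56.2, 26.1) on
  [17, 99] (matching the published donor pool's parameters and bounds —
  note the truncation brings the realized SD to ≈20 even though the
  untruncated scale parameter is 26.1); sex Bernoulli(31/58) independent
  of strain (no sex effect, matching the screening outcome; a `sex_effect`
  knob, default 0, exists to power the screen's detection tests);
  `ln(strain)` from the reference log-normal truth. One coupon per
  subject. A `right_censor_at` threshold (default off) caps strains to
  exercise the censored-likelihood path. Output in true or engineering
  strain to exercise the conversion path.
- **Rib-strain cases.** Per-case delta-v and age uniform over 20–80 km/h
  and 20–90 years; per-rib true strains log-normal (spread 0.35) around a
  median `0.006·exp(0.024·(Δv − 20))`, i.e. log-linear in severity from
  ~0.6% strain at the floor to ~2.5% at 80 km/h — the range over which the
  reference risk function sweeps from negligible to high per-rib risk, so
  fitted population curves are well identified. These values are the
  package's choice of a realistic scenario; real crash-simulation output
  additionally varies restraint parameters, pulse shapes, and intrusion,
  none of which is emulated.

Passing the end-to-end tests therefore shows the *pipeline* is correct and
well calibrated under its own assumptions (log-linear age effect,
independent ribs, log-normal spread); it does not validate those
assumptions against physical test or field data.

## Numerical choices and edge cases

- Log-logistic CDF evaluated as `expit(α·(ln s − ln λ))` and Weibull as
  `-expm1(-exp(z))` for float stability in the tails; inversions are
  closed-form per family (verified against bisection in the tests).
- Fits require n ≥ p+1 (positive residual degrees of freedom for the
  scale), allowing the two-point no-covariate case whose MLE is the exact
  two-point normal solution.
- Probabilities in CSV outputs are written at 12 significant digits;
  model JSON round trips bit-exactly.
- Monotonicity properties are asserted on grids kept below the range where
  the CDF saturates to 1.0 in double precision.
- Every simulation entry point takes an explicit integer seed
  (numpy `default_rng`); identical seeds reproduce identical tables.

## Problem sizes

Simulation-based checks use: 200 replicate fits (n = 58) for Wald-coverage
of the age coefficient; 500 replicates for ANOVA screen power/type-I rates
and for confidence-band coverage; 1,000 random vectors for
Poisson-binomial enumeration equivalence; 200 synthetic crash cases for
the end-to-end population-curve property and 1,000 cases for the
logit-truth recovery. These sizes put Monte-Carlo error comfortably inside
the asserted bands.

## Known limitations

Tensile, medium-strain-rate (0.5 /s) failure data only — no strain-rate
scaling, no compressive/shear criteria. Rib independence in the
Poisson-binomial step ignores load-path correlation between neighbouring
ribs. Alternative published rib risk functions are supported only as
user-supplied parameter sets. No FE solver coupling: strain extraction
happens upstream of this package.
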