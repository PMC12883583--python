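# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `riclpm`, in the
spirit of a model-documentation page: what is computed, under which
assumptions, and what the tests do and do not establish.

## The RI-CLPM and its parameterization

The random-intercept cross-lagged panel model separates stable
between-person differences from within-person dynamics. For two constructs
over `T` waves (variable order interleaved: `a_1, b_1, a_2, b_2, ...`):

- **Between part.** Two random intercepts, one per construct, each loading
  1 on every wave of its construct; their 2×2 covariance `psi` is free. The
  off-diagonal of `psi`, standardized, is the intercept correlation `r` —
  the "stable association" between constructs.
- **Within part.** Wave-specific latent fluctuations with loading 1 and
  measurement-error variance fixed to 0, so `y_t = mu_t + eta + w_t`
  exactly.
- **Lag-1 regressions.** Per lag a free 2×2 matrix `B_t` (diagonal:
  auto-regressive; off-diagonal: cross-lagged). Coefficients are
  wave-specific, not time-constrained, because uneven lag durations
  (1.0–6.7 years here) make equality constraints substantively wrong;
  equality-constrained variants can be imposed by fixing `B_t` entries
  equal in a custom index, but are not the default.
- **Covariances.** Free wave-1 within covariance `theta_1` and free
  innovation covariances `theta_t` (waves 2..T); their correlations are the
  cross-sectional residual associations.
- **Means.** Saturated: one free mean per observed variable. This is the
  conventional RI-CLPM choice and yields df = p(p+3)/2 − n_free = 37 at
  T = 6 (p = 12, n_free = 53).

Implied moments follow the linear-chain construction: with `L` the block
lower-triangular map from stacked innovations to within-components
(`L[t,s] = B_{t-1}···B_s`), the implied covariance is
`Sigma = J psi J' + L D L'` with `J` stacking unit loadings and `D` the
block diagonal of `theta_1..theta_T`.

Covariance blocks are optimized through Cholesky factors with
log-transformed diagonals (floor `exp(-30)`), keeping the parameter space
unconstrained while allowing `psi` to reach the positive-semidefinite
boundary in practice.

### ALT-SR variant

The autoregressive latent trajectory model with structured residuals adds a
random linear slope per construct, with loadings fixed to years since that
construct's first wave, and a joint 4×4 intercept/slope covariance. Two
identified mean structures are offered:

- `means="saturated"` (default): the 2T observed means stay free and the
  slope means are fixed at 0 — only between-person *variance* in trends is
  added. Free slope means would be exactly collinear with free observed
  means (any slope mean shifts wave means by `lambda_t * mu_s`, which the
  saturated means absorb), so they are not estimable in this structure.
  With zero slope variances this variant reduces to the RI-CLPM implied
  moments exactly, which the tests verify. 60 free parameters, df = 30 at
  T = 6.
- `means="structured"`: 4 factor means (intercepts and slopes) replace the
  free observed means — the textbook growth-model mean structure. 52 free
  parameters, df = 38 at T = 6.

## Estimation

**FIML.** Rows are grouped by missingness pattern; each group contributes
the Gaussian log-density of its observed sub-vector under the matching
sub-moments. This is the standard direct (casewise) ML treatment of MAR
missingness. Groups are processed in stacks of equal observed-variable
count so Cholesky factorizations run through batched LAPACK; the cost per
likelihood evaluation depends on the number of distinct patterns, not on n.

**Gradients.** Exact, by reverse-mode accumulation: the per-pattern
gradients with respect to (mu, Sigma) are closed-form, and an adjoint of
the implied-moment construction (through the chain matrix, the Cholesky
factors and the loading structures) maps them to the packed parameter
vector. A finite-difference check is part of the test suite.

**Optimization.** L-BFGS on the mean (per-row) negative log-likelihood,
followed by damped Newton refinement with an eigenvalue-regularized
finite-difference Hessian and a unit trust region. The refinement matters
near variance-component boundaries (e.g. ALT-SR slope variances collapsing
to zero on RI-CLPM data), where quasi-Newton methods stall in flat
directions. Convergence is declared when the per-row gradient infinity norm
falls below 1e-5 (with the likelihood change correspondingly below ~1e-9);
non-convergence and active variance floors are flagged on the result, never
raised. Starting values are moment-based (pairwise-complete covariances,
between-person variance split, within-block lag-1 regressions); perturbed
restarts run on non-convergence, or from the outset via `n_starts`.

**Saturated and baseline models.** The saturated (unstructured-moments)
FIML solution uses the closed form on complete data; under missingness a
batched EM pass warm-starts a quasi-Newton polish on (mu, chol(Sigma)). The
independence baseline factorizes per variable and is closed-form. Baseline
df = p(p+3)/2 − 2p = 66 at T = 6.

**Standardization.** Lagged coefficients are rescaled by model-implied
within-component standard deviations; covariances become correlations.
Note a property of this model class that is easy to get wrong: with
loadings fixed to 1, the RI-CLPM is closed under a *common* affine
rescaling per construct, but **not** under per-variable (per-wave)
rescaling — a wave-specific scale change would require wave-specific
intercept loadings. Consequently standardized estimates are exactly
invariant to construct-level affine maps (tested to 1e-6), while per-wave
min-max normalization — whose sample minima and maxima are noisy order
statistics — perturbs estimates slightly. This is an inherent property of
the published normalization procedure, not of this implementation; its
practical effect on the synthetic cohort is documented below.

**Standard errors.** Default "conventional robust" = Huber–White sandwich
`A⁻¹ B A⁻¹ / n`, with `A` the mean per-row negative Hessian
(finite-differenced analytic gradients, step 1e-5 relative) and `B` the
mean outer product of per-row scores (closed-form given finite-difference
moment Jacobians, step 1e-6). Observed-information SEs are available by
flag and agree within ~15% under correct specification (tested at
n = 10,000). SEs of standardized quantities use the delta method with
central differences on the packed vector; 95% CIs are estimate ± 1.96·SE.

## Fit indices

χ² = 2(ll_sat − ll_model) with the central χ² p-value; RMSEA =
sqrt(max(χ²−df, 0)/(df·(n−1))) with a noncentrality-inversion CI (coverage
configurable; default 95% to match the reference analysis's label, though
90% is the field convention); CFI with zero-floored noncentralities; TLI
unclamped by default (configurable); SRMR as the RMS of correlation-metric
residuals over the lower triangle including the diagonal, mean structure
excluded. Under missingness the saturated-model FIML moments serve as the
sample moments for SRMR, keeping it well-defined under MAR. The RMSEA
(n−1) vs n denominator conventions agree to 3 decimals at cohort-scale n.
Adequacy flags: RMSEA ≤ 0.05, CFI ≥ 0.95, TLI ≥ 0.95 (inclusive),
SRMR < 0.08 (strict), exactly as printed conventions state them.

## Reporting

Lag durations come from the wave schedule: AR paths span same-construct
consecutive median ages; CL paths span the *predictor's* age at wave t to
the *outcome's* age at wave t+1 (inferred from the reference table's
printed age pairs, e.g. adiposity 9.8 → depressive symptoms 12.8, so the
two directions of the same lag have different durations). Yearly estimates
are β/Δt (CI bounds likewise), assuming linear additivity of effects over
time; display rounding is half-away-from-zero to 2 decimals with full
precision retained in CSV. Significance marking = 95% CI excluding zero.

One caveat the tests encode: the reference table's printed yearly column
was computed from unrounded coefficients, so recomputing it from the
*printed* two-decimal betas reproduces 14 of 20 rows exactly and all 20
within one display unit; the divergent rows sit exactly on rounding ties
(e.g. 0.84/1.6 = 0.525). The package's own tables are internally exact by
construction.

## The synthetic cohort

`alspac_like_truth()` defines the default data-generating truth on the
normalized [0, 1] scale:

- **Dynamics.** Lagged coefficients calibrated so that their *standardized*
  values equal the published magnitudes (adiposity AR 0.54–0.84,
  depressive-symptom AR 0.12–0.38, cross-lagged paths 0.03–0.13); since the
  two constructs have unequal within-variances, the raw cross-lagged
  entries are the targets rescaled by the within-SD ratio. Innovation
  correlations follow the published wave-specific residual correlations
  (−0.08 to 0.11); the intercept correlation is 0.11.
- **Variances.** Within-person variances constant over waves (0.016 for
  depressive symptoms, 0.006 for adiposity on the normalized scale) with
  innovations absorbing the AR-propagated remainder, so standardized = raw
  for AR paths. Between-person variances 0.008/0.009 give intercept shares
  of ~1/3 (symptoms) and ~0.6 (adiposity) — adiposity is the more
  trait-like construct. Magnitudes were chosen so that the implied raw-scale
  medians and ranges match the cohort's descriptive table.
- **Raw links.** Questionnaire totals: normalized → sqrt-scale [0, √26],
  squared, rounded to integers, clipped to [0, 26] (a floor exists, as for
  the real instrument). Marker: normalized → ln-scale [ln 0.6, ln 28.5],
  exponentiated (right-skewed, strictly positive).
- **Missingness.** Per-wave targets follow the cohort profile (symptoms
  15→54%, marker 50/51/24/36/40/53%). Under MAR, wave 1 is MCAR and later
  waves have missingness log-odds linear in the *observed* previous-wave
  raw score of the same construct (defaults: +0.08 per symptom point,
  +0.10 per kg/m²; higher scores → more dropout), with the intercept
  calibrated per wave on the realized sample so marginal rates hit their
  targets. Rows whose previous value is missing revert to the marginal
  rate. A single seed governs all draws in a documented order (intercepts,
  wave-1 fluctuations, innovations per wave, then missingness uniforms
  construct-by-construct), so fixtures are byte-stable.
- **Debug channel.** `return_latent=True` exposes the latent intercepts and
  within-components for oracle tests (e.g. OLS of wave-t+1 components on
  wave-t components recovers `B_t`); they are never written to fixtures.

What the generator does *not* emulate: item-level questionnaire responses,
non-normal within-person dynamics, time-varying confounding, attrition
correlated across constructs. Passing recovery tests on this cohort shows
the estimator is correct under its assumptions, not that those assumptions
hold in any real cohort.

## Validation design and problem sizes

The package's stochastic self-checks run on **model-scale** panels
(`truth.model_scale()`, i.e. the exact Gaussian structure, complete data):

- single-fit recovery at n = 5,000: every standardized AR/CL estimate
  within ±0.05 of truth (typical max error ≈ 0.03; path SEs 0.01–0.03);
- bias: mean error over 100 replicates at n = 2,000 below 0.02 per path
  (measured ≈ 0.008);
- χ² calibration: mean statistic over 200 replicates at n = 2,000 within
  37 ± 2.

They are run on the model scale deliberately. Pushing recovery studies
through the raw links and per-wave min-max normalization superimposes two
known distortions — the integer rounding/floor of the questionnaire link
(measurement error the zero-error model cannot absorb) and the per-wave
scale jitter of sample extrema discussed under *Standardization* — which
bias AR-type paths by up to ~0.04 *at any sample size*. These are
properties of the emulated preprocessing procedure, not estimator defects;
the full raw pipeline is validated end-to-end by its own checks (realized
missingness rates, latent-moment agreement, OLS-on-latents recovery,
deterministic artifacts), and its recovery error is reported as a separate
quantity by the acceptance script (median path error ~0.01–0.03 at
n = 5,000 with full MAR missingness; the worst path — typically a late
adiposity AR coefficient, whose scale is most sensitive to the noisy
per-wave extrema — can deviate by 0.05–0.20).

## Numerical details and edge cases

- Quartiles for outlier fences use linear interpolation (the numpy
  default), logged in the preprocessing record since fences depend on the
  estimator; fences are strict inequalities (values exactly at
  Q3 + 5·IQR are kept). Masking is per construct × wave, before transforms,
  so a masked outlier can never raise a transform domain error.
- Min/max for normalization are computed after masking and transform, per
  variable, and stored for exact inversion.
- A singular implied sub-covariance during optimization yields an
  optimizer-safe sentinel, not an exception; degenerate inputs (constant
  series, all-missing series, < 4 values for quartiles, < 2 distinct
  values for normalization) raise or warn as documented in docstrings.
- Rows observing no variable are excluded from the likelihood (and
  counted); participants lacking a whole construct are excluded by the
  inclusion rule (≥ 1 value per construct), and the count is logged.
- Ties in display rounding go half-away-from-zero; CSV artifacts keep full
  precision.

## Known limitations

- No Satorra–Bentler-style scaled χ²; "robust" refers to sandwich SEs only.
- No imputation, no item-level scoring, no covariates; exactly two
  constructs per fit; lag-1 dynamics only.
- The ALT-SR is fit with freely varying residual dynamics; equality with
  any particular published ALT-SR specification is not asserted.
- Delta-method SEs for standardized quantities assume differentiability;
  at exact variance boundaries they are reported as missing with a warning.
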