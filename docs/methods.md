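# Methods

## The model

`pubsitar` derives individual pubertal ages from longitudinal growth and
development data with the SITAR (SuperImposition by Translation And
Rotation) shape-invariant growth model.  For individual *i* measured at
ages *t<sub>ij</sub>* (years),

```
y_ij = α_i + h( e^{γ_i} (t_ij − c − β_i) + c ) + δ_i (t_ij − t_adult)_+ + ε_ij
```

* **h** — a single natural cubic spline "mean curve" shared by the sample,
  with internal knots at equally spaced quantiles of the age distribution,
  boundary knots at the observed age range, and linear extrapolation
  beyond them (zero second derivative at the boundaries).
* **α (size)** — vertical shift, outcome units.
* **β (timing)** — horizontal shift, years; the individual's relative
  pubertal timing.
* **γ (intensity)** — log age-scale stretch.  The stretch pivots at the
  centre *c* of the observation window (the mean observed age), making γ a
  local rotation of the curve.  An uncentred stretch (pivot at age 0)
  dilates transformed ages by |t|·sd(γ) — about ±2 y near a male growth
  spurt — which in testing produced a systematic ~0.1 y late bias in the
  fitted age at peak velocity and occasional degenerate optima; centring
  removed both.  This matches the standard SITAR parameterization (the age
  offset in the reference implementations).
* **δ (post-growth)** — individual adult slope, applied beyond
  *t<sub>adult</sub>*, taken as the **last internal knot**.  (With the
  upper *boundary* knot as onset the regressor `(t − t_adult)_+` would be
  zero for every observation and the effect unidentifiable.)
* **ε** — i.i.d. Gaussian residual, SD σ.

The random-effect vector (any non-empty subset of α, β, γ, δ) is Gaussian
with unstructured covariance **Ω**.  Model variants mirror the field's
practice: height uses {size, timing, intensity}; weight and BMC add the
post-growth slope; ordinal development scores (Tanner stages, voice
breaking, axillary hair) use the reduced {timing, intensity} model,
because all individuals traverse the same bounded scale, with the stage
score treated as a continuous response.

### Estimation

Iterated first-order conditional linearization (Lindstrom–Bates):

1. **Penalized nonlinear least squares** — Gauss–Newton updates of the
   fixed spline coefficients and all individual effect modes jointly,
   minimizing `Σ‖y_i − f(c, u_i)‖² + Σ u_iᵀ Δ⁻¹ u_i` with Δ = Ω/σ², with
   step halving.
2. **Variance-component update** — the model is linearized about the
   modes and the profiled marginal Gaussian log-likelihood (fixed effects
   and σ² profiled out in closed form via the Woodbury identities) is
   maximized over the log-Cholesky factor of Δ with L-BFGS-B, using the
   analytic gradient ∂nll/∂Δ = ½ Σᵢ (Zᵢᵀ Vᵢ⁻¹ Zᵢ −
   Zᵢᵀ Vᵢ⁻¹ rᵢ rᵢᵀ Vᵢ⁻¹ Zᵢ / σ̂²) chained through the parameterization
   (the profiled fixed effects and σ̂² contribute nothing by the envelope
   theorem).  Exact gradients matter here: finite differences stall at
   their noise floor on nearly flat likelihood directions.

The steps alternate until the marginal log-likelihood changes by less than
`tol` (default 1e-7 relative), with a minimum of 4 outer iterations.  The
starting point matters: effect modes are initialized by per-individual
ridge regression of OLS residuals on the effect Jacobian at u = 0, and the
initial effect scales are deliberately **doubled** — shrinking an
overstated variance is reliable, while understated timing variance can
trap the outer loop in a degenerate optimum that absorbs timing variation
into σ.  All per-individual linear algebra is batched over individuals, so
a cohort of 2 000 children fits in a few seconds on one core.

ML (not REML) is used throughout; BIC = −2·loglik + p·log(n) with
p = (n_knots + 2) + q(q+1)/2 + 1 and **n = number of individuals** (a
documented switch allows observations).  Knot counts 2–5 are compared by
BIC in `select_model`; ties go to fewer knots.

The fit runs internally on age offsets from the youngest observation,
quantized at nanoyear resolution, and maps knots, pivots and the
intercept back to absolute age afterwards.  Datasets that differ only by
a global time translation therefore pose bitwise-identical internal
problems, making the fit *exactly* translation-equivariant — without
this, float rounding of the shifted ages is amplified along flat
likelihood directions of weakly identified variants (see limitations)
into visible variance-component differences.

Empirical-Bayes (shrunken) effect predictions come from the final
linearized model.  Their sample variance is at most the corresponding Ω
entry; their mean is zero only up to sampling noise (~SD/√n), because the
fixed-knot spline cannot absorb an arbitrary translation exactly.

### Landmarks and pubertal ages

* Height/weight/BMC: **age at peak velocity** — argmax of the analytic
  first derivative of the fitted mean curve (dense 0.01 y grid + bounded
  local refinement).  A maximum on the boundary raises a "no interior
  peak" error.
* Tanner pubic hair / breast / genitalia: mean-curve **crossing of 3.0**
  (entry into stage 3, root-found to 1e-3 y); voice breaking (3-point
  scale) crosses **2.0**; axillary hair (2-point) crosses **1.5** — the
  midpoint "event" boundary of each scale.  All levels are configurable;
  the choice of entry-into-stage-3 rather than stage-3 midpoint is an open
  convention and is exposed as a parameter.
* Menarche: the **first reported** onset age across questionnaires, used
  as-is.
* Individual pubertal age = landmark age + the individual's timing BLUP.
  (The γ-rescaling of individual landmarks is deliberately not applied;
  the timing effect alone defines relative pubertal age.)

Inconsistent (regressing) stage reports are retained for all measures
except voice breaking, where observations below the individual's running
maximum are removed before fitting.  A ±5 SD visit-level outlier filter
(per sex, occasion and measure) supports the anthropometric sensitivity
analysis; it reports the count and percentage removed.

Ages are stored as months in all data files and converted to years for
modelling; the model is equivariant to the time unit (a pure rescale of
the timing components), so this is a storage convention only.

## The synthetic cohort generator

No individual-level cohort data are distributable (the emulated study's
data are managed-access), so the generator produces cohorts from the
SITAR generative model itself with known ground truth:

* **Design** — 9 clinic visits (~7.5–17.8 y; height, weight; BMC at the
  five DXA clinics only) and 9 questionnaires (~8.1–17.0 y; Tanner pubic
  hair in both sexes, breast in females, genitalia in males; voice from
  the second questionnaire; axillary hair from the third).  Exact ages are
  uniform in a bounded window around each nominal visit (SD 2 months).
  The bounded window makes the population age range finite, so the
  fitter's knot rule (quantiles + observed range) has a stable population
  analogue; the generator places its curve knots by exactly that
  population rule.
* **Growth curves** — realistic sigmoids (childhood growth switching off
  in late adolescence plus a logistic pubertal spurt) projected onto the
  natural-spline basis.  The generator is thus the generative inverse of
  the fitted model, and its analytic peak-velocity age is an exact oracle.
* **Development curves** — monotone logistic latents from 1 to K
  (K = 5 Tanner, 3 voice, 2 axillary), plus Gaussian latent noise
  (SD ~0.3), thresholded at half-integers.  With the scale midpoint as
  landmark level, the latent crossing age is exactly the onset parameter
  plus the individual's timing shift.  A configurable fraction of reports
  (default 5%) regresses by one stage, emulating inconsistent responses.
* **Timing structure** — one latent factor η per child;
  β_m = timing_sd_m·(λ_m·η + √(1−λ_m²)·noise) with default loading
  λ = √(cross-measure correlation), giving equicorrelated measure
  timings (default 0.5; observed studies report ~0.2–0.8).
* **Sex-specific means** — landmark ages are encoded in the curves:
  females from breast ~11.5 y to menarche ~12.7 y, males from pubic hair
  ~12.6 y to voice breaking ~14.2 y, peak height velocity ~11.8/13.5 y
  (F/M).  Timing SDs are 0.9–1.2 y by measure, matching the 0.7–1.2 y
  between-individual SDs such cohorts report.  The emulated study reports
  no variance components or random-effect covariances, so effect
  magnitudes (height: size 3 cm, intensity 0.15, residual 0.8 cm) are
  calibrated to those timing SDs and to plausible curve geometry only.
* **Covariates** — a standardized puberty GRS correlated with η (default
  0.25, consistent with reported GRS effects of ~0.24 y/SD on timing); an
  adiposity GRS loading on fat mass; and a small linear structural model
  maternal BMI → fat mass index → latent timing (paths 0.4, −0.35 y/SD
  direct, −0.2 y/SD confounding) with known closed-form adjusted and
  unadjusted regression slopes.  Lean mass index correlates 0.45 with fat
  mass index and carries no direct effect.  Remaining confounders
  (maternal age, education, parity, smoking, child energy intake) are
  structurally inert noise.
* **Menarche** — true age = sex mean + timing shift; reported with recall
  noise (SD 0.25 y) at every returned questionnaire after occurrence;
  derivation takes the first report.

What the generator does **not** emulate: informative missingness
(attrition correlated with exposures), reporting heaping and digit
preference, secular trends, non-Gaussian residuals, skeletal maturity,
and genotype-level data (the GRS is simulated directly as a standardized
score).  Passing tests therefore demonstrate correctness of the
estimators under a well-specified model and realistic noise, not
robustness to those real-data pathologies.

## Validation design and problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline at desk
scale: parameter recovery at 500 children × 9 visits per sex; the exact
linear-mixed-model reduction on a 20-child toy set against a closed-form
GLS oracle (golden-section search over the variance ratio, agreement to
1e-4); ordinal landmark recovery at n = 500; translation equivariance of
all nine derived measures at n = 120 per sex; correlation propagation at
n = 2 000 (one-factor loadings √0.3, √0.5, √0.7); regression identities
at n = 2 000 under loading 1; the outlier filter on a constructed
996 + 4 sample; and BIC knot-selection consistency over 20 replicates of
n = 1 000 generated from a 3-knot curve.  These sizes keep the whole
validation within minutes on one core while leaving Monte-Carlo error
well inside each tolerance.

## Numerical choices and degenerate inputs

* Natural-spline basis in the truncated-power form with analytic first
  and second derivatives; velocity comes from spline coefficients, never
  finite differences.
* Log-Cholesky parameterization keeps Ω positive semi-definite; diagonal
  log-scales are bounded in [−12, 8] so near-zero variance components
  (e.g. noiseless data) remain numerically safe.
* Non-convergence within `max_iter` returns the fit flagged
  `converged=False` with a warning; `select_model` skips non-converged
  candidates and errors only if none converge.
* Individuals with a single observation contribute through the fixed
  effects and receive heavily shrunken BLUPs.
* Landmark failures (no interior velocity peak; level never crossed) are
  flagged per measure and sex; derivation continues for the others.
* The 95% CIs are normal-approximation (β ± 1.96·SE); no
  multiple-testing adjustment is applied, matching per-model reporting.
* Missing dosages are mean-imputed per SNP by default (a flag switches to
  per-individual exclusion with a reduced divisor).

## Known limitations

* The marginal likelihood is the first-order (Lindstrom–Bates)
  approximation, not adaptive quadrature; variance components carry a
  small (few percent) downward bias at 9 visits per child.
* The four-effect model on the five-visit BMC schedule leaves about one
  residual degree of freedom per child: its variance components sit on a
  likelihood plateau (log-likelihood changes of ~0.005 across parameter
  changes orders of magnitude larger than their reporting precision).
  Point estimates of Ω for that variant should be read with their
  (large) uncertainty in mind; BIC, landmarks and timing BLUPs are far
  better determined.  Three internal knots is the default for BMC — the
  most the five-visit schedule supports stably.
* Ordinal scores are modelled as continuous; the fitted mean curve
  approximates the expected stage, which is compressed near the floor and
  ceiling of the scale.  Crossing landmarks at the scale midpoint are
  accurate to ~0.1 y; coarser scales (axillary hair's 2 points) give
  noisier timing BLUPs, mirroring the imprecision such indicators have in
  practice.
* Outcome and age transforms (e.g. log scales) are not applied by
  default; the fitting interface accepts any pre-transformed series.
* The pipeline models each measure independently; no joint multivariate
  SITAR fit is attempted.
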