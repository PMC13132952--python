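# Methods

## Model family

Every model in `twinsem` is a *source-loading model*: the stacked
observed vector of one twin pair is x = μ(θ) + L(θ)z with z ~ N(0, I),
so the implied covariance Σ = LL′ is positive semi-definite for any
admissible θ. Variance components enter through the tags on the source
columns:

- **A (additive genetic).** Co-twin genetic sources correlate r̄ = 1 in
  MZ and r̄ = 0.5 in DZ pairs. This is implemented by source splitting:
  each twin's genetic source is √r̄·z_common + √(1−r̄)·z_unique, which
  reproduces the cross-twin genetic covariance r̄·aa′ exactly while
  keeping every source an independent standard normal.
- **C (shared environment).** One source loads both twins identically.
- **E (nonshared environment).** Each twin has their own source; E also
  absorbs measurement error and is therefore mandatory in every
  configuration.

Means are equated across co-twins and across zygosity groups, the
standard assumption of the classical twin design (twin order within a
pair is arbitrary, and zygosity should not shift trait levels).

### Cholesky ACE/AE decomposition

For one phenotype at three waves, each included component contributes
the square of a free 3×3 lower-triangular path matrix. Free parameters:
6 paths per component plus 3 means (AE: q = 15; ACE: q = 21).
Standardised shares divide each component's diagonal by the total
phenotypic variance; for AE models the implied cross-twin correlations
are rMZ = a² and rDZ = a²/2 per wave, an identity used as an internal
consistency test. The sign indeterminacy of Cholesky paths is resolved
by bounding diagonal paths at zero (off-diagonals stay free) — a pure
reparameterisation with identical fit. AE-vs-ACE selection minimises
AIC = −2lnL + 2q, with ties (|ΔAIC| < 1e−6) going to the simpler AE
model.

### Genetically informative RI-CLPM

Two traits (X = wellbeing, Y = a life-event cluster) at three waves.
Each trait splits into a random intercept (loadings fixed at 1 on all
waves) and within-person deviations with

    w₁ = s₁,  w₂ = T₁w₁ + s₂,  w₃ = T₂w₂ + s₃,

where T_t = [[β_x, γ_xy], [γ_yx, β_y]] holds the autoregressive and
cross-lagged paths of transition t. The random-intercept block, the
wave-1 deviation and both innovation blocks are each decomposed into
per-component 2×2 lower-triangular Cholesky factors over (X, Y); a trait
that excludes a component has its row/column structurally zeroed, so a
C component touching only Y contributes one variance and no cross-trait
path. Free parameters for AE/AE: 4 levels × 2 components × 3 entries
+ 8 lagged paths + 6 means = 38; ACE on Y adds one C entry per level
(q = 42).

Design choices where the architecture was genuinely open:

- **Transmission is phenotypic**: the lagged paths act on the total
  within-person factors, not separately on their A/E parts. Later-wave
  within-person variance therefore mixes transmitted prior-wave variance
  with new wave-specific genetic and environmental innovations.
- **Innovation blocks are estimated freely at waves 2 and 3** (not
  equated across waves), and lagged paths are free per transition,
  matching wave-specific reporting; equality constraints can be imposed
  through the generic parameter-fixing mechanism.
- **Cross-trait covariance is carried within each component block** at
  the RI, wave-1 and innovation levels through the 2×2 Cholesky
  off-diagonal.

Because every loading is fixed at one, the implied observed variance at
wave w is exactly var(RI) + var(w_w); the reported RI share is
var(RI)/(var(RI) + var(w_w)), and the RI component split divides each
component's RI variance by the total RI variance. Standardised lagged
paths are raw × SD(predictor factor, wave w) / SD(outcome factor, wave
w+1), with the factor SDs taken from the lag recursion.

Three waves is the minimal panel for this model; local identification
is checked empirically (`identification_check`): the Hessian of −lnL at
the generating parameters on a large simulated sample has
smallest/largest eigenvalue ratio ≈ 2e−2, comfortably positive
definite, so all 38 parameter directions are informed by the data.

## Estimation

**Raw-data FIML.** Each pair-row contributes
k·ln2π + ln|Σ_obs| + (x−μ)′Σ_obs⁻¹(x−μ) over its observed entries; rows
with no observed values are dropped. Rows are grouped by missingness
pattern and reduced to per-pattern sufficient statistics (n, mean,
scatter), making the cost per likelihood evaluation one Cholesky
factorisation per pattern irrespective of sample size; the grouped value
equals row-by-row evaluation to floating tolerance (tested). A
numerically singular Σ returns a large finite penalty (1e12) to the
optimizer and is flagged.

**Optimisation.** Bounded L-BFGS-B on raw path coefficients (never on
variances, so implied components are non-negative by construction), with
multi-start: the first start is a data-driven heuristic (sample means;
component diagonals at √(variance/k) for k components, RI fraction 0.3
for the RI-CLPM; lagged paths at 0.2 autoregressive / 0 cross-lagged),
the rest are jittered copies (relative scale 0.2, seeded). Convergence
uses ftol 1e−11 on −2lnL and a projected-gradient check; a gradient norm
above 1e−4 (relative) raises a warning. On complete study-scale data the
likelihood surface has shown a single optimum across multistarts, so the
recovery harnesses default to the heuristic start only.

**Uncertainty.** Standard errors come from the inverse numerical Hessian
of −lnL (`statsmodels.tools.numdiff.approx_hess`); a non-positive
definite Hessian or an estimate on a box bound flags the SEs unreliable.
Derived quantities (standardised shares and paths) get delta-method SEs
through the same parameter covariance; profile-likelihood intervals
(bisection on the χ²₁ = 3.84 boundary) are available for raw parameters
and for twin correlations, and agree with Wald intervals to ~20% at
n = 2000 in testing.

**Reference models and fit statistics.** The saturated model frees the
mean vector and full covariance per zygosity group (closed form on
complete data, FIML-optimised mean + Cholesky(Σ) otherwise); the
independence model (free means, diagonal covariance) factorises across
variables and is closed form even under missingness. CFI, TLI and RMSEA
follow the standard likelihood-χ² definitions; RMSEA uses the
multi-group convention √(G·max(T−df,0)/(df·(N−G))) with G = 2 — noted in
the output metadata because conventions without the factor G differ by
√G. CFI and TLI are clamped to [0, 1]. Likelihood-ratio tests clamp
Δχ² at zero and warn if the nested model fits better than the full
(optimizer failure suspected).

## Descriptive layer

Phenotypic correlations treat twins as individuals with pairwise-complete
deletion; p-values are naive two-sided t-transform values and do **not**
correct for family clustering (the screening step only needs magnitudes,
and this matches common practice for descriptive matrices). Twin
correlations are single-entry Pearson by default with a double-entry
option; CIs are Fisher-z (tanh(atanh r ± z/√(n−3))) by default with a
profile-likelihood alternative from an exchangeable bivariate-normal
pair model. Age residualisation regresses a measure on age per wave
across twins-as-individuals and keeps the result missing where age is
missing; identical ages fall back to mean-centering with a warning.
An event category is screened out of the twin analyses when no
same-wave correlation with wellbeing is both non-negligible
(|r| ≥ 0.10) and significant at α = 0.05 — requiring both conditions
keeps the null-data false-inclusion rate at the level of a 4.5-sigma
accident rather than the ~14% of a significance-only rule.

## Synthetic data: what it emulates and what it does not

The generator draws sources per pair and maps them through the same
loading matrices the estimator uses, so simulated data match the implied
moments by construction (verified against Monte-Carlo covariances). The
study-scale preset emulates the target cohort: 550 MZ + 890 DZ pairs
(≈ 1,094 MZ and 1,785 DZ twins), MCAR wave participation drawn from the
seven observed patterns with weights proportional to
(1132, 613, 179, 78, 710, 97, 70), co-twin-shared ages N(15.2, 1.9²),
N(16.9, 2.0²), N(19.6, 1.9²) per wave, and optional discretisation to
the bounded ordinal scales (affine rescale to a target mean/SD, round
half-up, clamp; half-up documented because the rounding rule affects
attenuation checks).

Generating parameters are fixed at the study conditions on a
unit-total-variance scale per trait and wave:

- wellbeing: RI variance 0.40 split 81% A / 19% E; within-person
  variance 0.60 per wave with wave-1 split 26% A / 74% E so the total
  wave-1 heritability is 0.48 (wave-specific totals 0.48/0.46/0.26 in
  the Cholesky preset, with cross-wave genetic correlations 0.7–0.8 and
  environmental correlations 0.15–0.2 giving phenotypic stability
  ≈ 0.4–0.5);
- negative dependent events: RI variance 0.35 split 70/30, within 0.65
  with 39.2% A (total heritability 0.50, inside the 47–55% range the
  prior decomposition of these events reports);
- negative independent events: A/C/E ≈ 0.18/0.41/0.41 overall,
  matching the reported ranges (A 12–25%, C 29–49%);
- standardized autoregression 0.25 (wellbeing) and 0.30 (events) —
  moderate within-person carry-over chosen once as plausible for
  two-year intervals; standardized cross-lags set to the published
  estimates (−0.11, −0.02, −0.08, −0.10 for dependent events;
  −0.01, −0.05, −0.01, −0.01 for independent events);
- cross-trait correlations −0.40 (RI level), −0.15 (wave-1), −0.10
  (innovations), reproducing same-wave phenotypic correlations ≈ −0.24.

Innovation variances are solved from the lag recursion so every
within-person factor hits its target variance exactly, which makes the
generating standardized paths and RI shares exact rather than
approximate. Recovery runs use continuous, complete data by default so
estimator bias is isolated from coarsening and missingness; a `realism`
preset switches both on.

What the generator does **not** reproduce: the true ordinal/count
likelihood (measures are multivariate normal before optional rounding,
so discretisation-robustness conclusions are about coarsening a normal,
not about genuinely ordinal data); non-MCAR dropout; cohort structure
within waves (ages are drawn i.i.d. per pair); sex effects;
gene–environment interaction or correlation. Passing recovery tests
therefore demonstrates correctness of the estimator under its own
assumptions, not robustness to their violation.

## Problem sizes and replication counts

The recovery harnesses use 50 replicates at 1,000 MZ + 1,500 DZ pairs
(Cholesky) and 50 replicates at the study scale of 550 MZ + 890 DZ
pairs (RI-CLPM); CI-coverage calibration uses 100 replicates at 500+500
pairs, LRT size 200 replicates of a bivariate nonshared-environment
model at 100+100 pairs, and AIC selection consistency 20 replicates at
1,000+1,000 pairs. Per-replicate seeds derive from one master seed via
`SeedSequence`, so every study is reproducible from a single integer.
Observed calibration: |bias| < 0.01 on all standardized quantities,
95% CI coverage ≈ 0.95, LRT size ≈ 0.055.

## Known limitations

- The 1–10 ladder and event counts are modelled as continuous Gaussian
  variables (no threshold/liability model), mirroring the linear
  treatment the analyses assume; heritability of coarsely discretised
  data is mildly attenuated (tested).
- Delta-method CIs for shares near 0 or 1 can cross the boundary and are
  clipped; profile intervals are preferable there.
- Descriptive p-values ignore family clustering (flagged above).
- No sex-limitation, definition-variable, moderation or non-MCAR
  mechanisms; at most three waves; bivariate RI-CLPM only.
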