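# Methods

## Structural models

The candidate bank contains nine sums of exponentials `a_px(t)` describing
the fraction of administered ¹³¹I activity in the thyroid at time `t` (hours
post administration). Every exponential term carries the physical decay
constant λ_phys = ln 2 / (8.022 d · 24 h/d) ≈ 3.60 × 10⁻³ h⁻¹ in addition to
its biological rate, so amplitudes `a_i` (dimensionless fractions) and rates
`λ_i` (1/h) are purely biological quantities. All parameters are constrained
non-negative. Eight of the nine functions satisfy `a_px(0) = 0`, reflecting
that no activity is in the gland at administration; the exception is `a4c`,
whose free amplitude `a1` represents residual blood-pool signal that the
neck-minus-thigh measurement does not remove, so `a4c(0) = a1` by
construction and this is deliberately not forced to zero.

Internally every model is held as a list of `(amplitude(θ), rate(θ))` term
pairs (symbolic, compiled to vectorized numpy with structural zeros pruned),
which gives three things for free: batched evaluation over patients,
analytic first and second derivatives with respect to the parameters (used
by the inner Newton steps and the Laplace determinant), and the closed-form
time-integrated activity

```
TIA(θ) = Σ_k A_k(θ) / (r_k(θ) + λ_phys),
```

valid because every effective decay rate is positive. The `a3b`/`a4c`
amplitude denominator `λ1 + λ2 − λ3` is computed as written; parameter
vectors within 10⁻¹⁰ of the singularity raise an error in direct evaluation,
while the fitter treats them as an infeasible (penalized) region so the
search can retreat rather than abort.

## Population model and likelihood

For patient `i` with structural vector `P_i`:

```
P_i   = TVP ⊙ exp(η_i),      η_i ~ N(0, diag(ω²))          (log-normal IIV)
y_ij  = model(f_ij, ε_ij),   ε_ij ~ N(0, σ²)               (residual model)
```

Residual models: proportional `y = f(1+ε)` (variance σ²f², the default),
additive (σ²), combined (σ²_add + σ²_prop f²), and exponential, implemented
as additive-normal on log observations with the log-normal Jacobian included
in the objective so that objective values remain comparable across residual
models on the same data.

The marginal likelihood is approximated by the Laplace method. With
ℓ_i(η) = −2 log p(y_i | η) p(η) (all 2π constants included),

```
−2 log L̂_i ≈ ℓ_i(η̂_i) − q log 2π + log det(H_i / 2),
H_i = ∇²_η ℓ_i(η̂_i),
```

where η̂_i is the per-patient inner optimum. The reported objective `of` is
the sum over patients; its additive constant convention (full Gaussian
constants, Jacobian for the exponential model) is fixed and identical across
all models, so AICc *differences* — the only thing model selection uses —
are unaffected by it. Inter-individual variances below 10⁻¹² are treated as
exactly zero: the corresponding η components are pinned at 0 and leave the
integral, which makes the ω² = 0 limit reduce exactly to the fixed-effects
likelihood.

The tests verify the Laplace values against an independent adaptive
Gauss–Hermite quadrature (96 nodes) of the exact marginal integral on small
instances for all four residual models; agreement is required within 0.5
units of −2 log L.

## Optimization

*Inner problem* (per patient, dimension ≤ 6): damped Newton with the exact
analytic Hessian, batched across all patients with per-patient damping and
step acceptance. Warm starts are taken from the previous outer iterate, but
each solve compares the warm start against the prior mode η = 0 and begins
from the better of the two, which makes the outer objective effectively
path-independent. Patients whose joint deviance at the start exceeds 10⁶
(structurally hopeless parameter regions visited by the outer search) are
not inner-optimized; their raw deviance is returned, keeping the objective
finite, smooth and decreasing toward feasible regions.

*Outer problem*: L-BFGS-B over `log TVP`, `log ω²`, `log σ²` (positivity by
construction; bounds keep exponentials finite). Objective values above 10⁹
are log-compressed by a monotone soft cap so that line searches can
interpolate through infeasible excursions. Multi-start search: starting
rates are drawn log-uniform on [10⁻⁴, 1] h⁻¹, amplitudes on [10⁻³, 1], with
ω = 0.5 and σ = 0.1 as variability starts. Every start gets a short
exploration budget; the few most promising candidates are polished to full
convergence with repeated L-BFGS restarts (resetting the quasi-Newton memory
escapes premature small-step terminations). The best converged objective
wins, ties broken by the lowest start index. All randomness flows from one
integer seed recorded in the results.

*Uncertainty*: the covariance of the estimates is the inverse Hessian of
−log L̂ at the optimum (central finite differences on the search scale, step
10⁻³), mapped to the natural scale by the delta method; the relative
standard error of each estimate equals the search-scale standard error.
Sampling importance resampling (SIR) provides a curvature-independent
check: draws from the multivariate-normal proposal centered at the estimate
are weighted by the full importance ratio — the posterior kernel
exp(−Δof/2) divided by the proposal density — and resampled without
replacement; with the ratio in place an exactly quadratic objective
reproduces the Wald interval, which the tests assert. An effective sample
size below 10% of the draws flags degenerate weights.

## Selection

`AICc = of + 2K + 2K(K+1)/(N−K−1)` with `K = 2p + 1` for a p-parameter
structural model (fixed effects, their variances, one residual variance) and
`N` the number of observations. Akaike weights are computed over the set of
gate-passing models only, after subtracting the minimum AICc for numerical
stability; the selected model is the highest-weight (lowest-AICc) member,
with near-ties (within 10⁻⁶) resolved toward fewer parameters.

The goodness-of-fit gate applies strict inequalities: max fixed-effect
RSE < 0.3, max random-effect RSE < 0.5, max |off-diagonal correlation| < 0.8,
convergence with a usable covariance. "Visual inspection of the fitted
curves" is automated as a residual-trend check: each observation is
standardized against the simulation-based marginal mean and SD under the
fitted model (1000 replicate cohorts, fixed internal seed, so the check is
deterministic), the standardized residuals are binned at the nominal
sampling times, and every bin must satisfy |mean z| < z_crit/√n_bin. Two
calibration choices matter here. First, centering on the typical-value
prediction instead of the simulated mean would bias the check: with
inter-individual CVs around 1 the marginal mean of the observations differs
materially from the curve at the typical parameters, so even the true model
would show a spurious "trend"; simulation-based centering makes mean z = 0
under the fitted model by construction. Second, the critical value is
Bonferroni-adjusted across bins at a family-wise level of 0.01: a plain
2/√n bound per bin would false-flag a correct model in roughly a quarter of
cohorts (six bins at ~5% each), whereas genuine misfit — e.g. a missing
blood-pool term at the 2-h sample — produces |mean z| many times the bound,
so the adjustment costs essentially no power. The check can be disabled, and
its per-bin table is reported in the gate details.

## Individual-fit comparator

The standard-procedure comparator fits `a3b` to each patient separately by
least squares on relative residuals `(y−f)/f` (the natural criterion under
proportional error), multi-start per patient with seeds offset by patient
index. An individual fit needs at least p+1 observations (K_max = N−1). One
residual variance shared across patients is then profiled by maximum
likelihood, which puts the pooled objective on the same −2 log L scale
(including constants) as the population fits; the pooled parameter count is
K = p × n_patients (3 × 73 = 219 for the default design), matching the
convention that the shared profiled σ² is not counted. Whether the original
analysis pooled σ² this way is not stated; only the AICc arithmetic, which
is unaffected, is checked against printed values.

## Synthetic cohort

The generator reproduces the study design: 53 patients sampled at
{2, 6, 24, 48, 96} h and 20 at {2, 6, 24, 48, 120} h, the first schedule-A
patient missing the 6-h sample — 73 patients, N = 364. Default generating
parameters are the published population estimates for `a4c`: fixed effects
a1 = 7.1 × 10⁻², λ1 = 7.9 × 10⁻² h⁻¹, λ2 = 6.7 × 10⁻² h⁻¹,
λ3 = 1.2 × 10⁻³ h⁻¹; inter-individual CVs 0.79, 1.1, 0.51, 1.0; proportional
residual SD σ = 4.8 × 10⁻². Printed CVs are converted to log-normal SDs by
the exact relation ω = √(ln(1+CV²)); since it is not stated whether the
printed values are CVs or ω itself (a common reporting shortcut), a
`cv_is_omega` switch supports the other reading, and recovery checks use
fixed effects and σ only, which are free of this ambiguity. Residual draws
that would make an observation non-positive are redrawn (not truncated) and
counted in the provenance sidecar.

What the synthetic cohort does *not* emulate: detector count-rate statistics
and background subtraction, covariate structure (age, disease, thyroid
volume), model misspecification of any kind, and deviations from nominal
sampling times. Passing tests therefore demonstrate that the pipeline
recovers the data-generating mechanism under its own assumptions at the
study's design size — not that those assumptions hold for any particular
clinic's data.

## Validation diagnostics

*VPC*: replicate cohorts are simulated from the fitted model under the
original design; observed 5/50/95th percentiles per nominal time are
compared with Monte-Carlo bands (default 500 replicates; fewer than 100
records a warning in the result).

*NPDE*: per patient, the simulation mean and covariance (default 1000
replicates) decorrelate the observed and simulated vectors via the symmetric
inverse square root (eigenvalues floored at 10⁻¹⁰ of the largest, with
regularized patients listed); each observation's rank among its decorrelated
simulations, with seeded uniform jitter of one rank to break ties, is mapped
through Φ⁻¹. Under a correct model the NPDE are ≈ iid N(0,1); the summary
carries mean, variance and a Shapiro–Wilk test.

*Residual-error sweep*: the selected model is refitted under the additive,
combined and exponential residual models and per-patient empirical-Bayes
TIAs are compared with the proportional fit (mean ± SD of relative
deviations); each variant's multi-start set includes a start seeded from the
reference estimates.

## Comparison metrics

For per-patient TIAs of a method against a reference:
`RD_j = (TIA_j − TIA_ref,j)/TIA_ref,j`,
`RMSE = √(SD² + mean²)` and `MAPE = mean |RD|`. The SD uses the
n-denominator convention by default, making RMSE exactly the root mean
squared RD (the identity is asserted in tests); the n−1 convention is
available via `ddof=1` and changes small-cohort summaries by a few percent.

## Problem sizes and defaults

Defaults follow the study where it states them: 1000 multi-starts per
population fit (`n_starts`), gate thresholds 0.3/0.5/0.8, N = 364 design.
The package's own reduced sizes, chosen to keep a desk-scale analysis
turnkey: 100 starts per model in the end-to-end selection runs and the
acceptance script (the exploration/polish scheme reaches the same optima on
this design well below 100 starts), 100 starts per patient for individual
fits, 500/1000 simulation replicates for VPC/NPDE, SIR with 2000 draws and
500 resamples. Exploration budget is 15–20 L-BFGS iterations per start with
the top 5 candidates polished.

## Known limitations

- Laplace is a second-order approximation; with very sparse per-patient data
  (4–5 points) and large IIV its likelihood can deviate from exact marginal
  likelihoods by more than the quadrature-checked small-instance bound,
  although selection differences of tens of AICc units dwarf this.
- Random effects are diagonal (no ω covariance), matching the generating
  model but not estimable correlations between parameters.
- No covariate submodels on the fixed effects.
- Empirical-Bayes TIAs inherit shrinkage: with sparse individual data and
  high IIV, individual TIAs are pulled toward the typical value.
- The individual-fit comparator implements the full-schedule fit only, not
  the one- and two-measurement approximation formulas used for sparse
  clinical schedules.
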