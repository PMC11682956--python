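# Methods

`serinepkpd` implements a population pharmacokinetic-pharmacodynamic (PK-PD)
model of orally administered L-serine (AST-001) in children with autism
spectrum disorder, together with the machinery around it: a synthetic trial
generator, a nonlinear mixed-effects estimator, simulation-based diagnostics,
and a weight-tiered dose-scenario engine.  Time is measured in days, amounts
in mg, concentrations in ug/L, and the clinical endpoint is the
K-VABS-II-ABC adaptive-behavior composite score (points).

## Structural model

**Pharmacokinetics.**  A two-compartment disposition model with zero-order
absorption of duration `D1` and linear elimination, parameterised as apparent
clearances/volumes (`CL/F`, `V1/F`, `Q/F`, `V2/F`).  The plasma response to
each dose event is the closed-form bi-exponential solution to a zero-order
input; full profiles are superpositions over the dose-event list, so BID
regimens with titration and crossover phases are exact, not gridded.
Endogenous serine production is not modelled: the model describes exogenous
drug only.  Pediatric parameters are obtained by allometric scaling of the
(adult) reference values with fixed exponents 0.75 on clearances and 1.0 on
volumes; weight is the only PK covariate and the PK carries no
inter-individual random effects here because it is fixed from a prior
analysis (the "population PK parameters" approach).

**Effect compartment.**  The clinical response lags exposure by months, so
plasma is linked to a hypothetical effect site by

    dCe/dt = ke0 (Cp - Ce),  Ce(0) = 0.

With the default `ke0 = 0.0065/day` the equilibration half-life
`ln 2 / ke0` is about 15 weeks — the drug effect is still building at the
end of a 12-week treatment period.  `Ce` is computed by exact piecewise-
analytic convolution of the closed-form plasma pieces with the first-order
kernel (`effect_site_from_regimen`); a generic grid integrator
(`effect_site_concentration`, exponential-integrator update, default step
0.25 day) is provided for arbitrary plasma inputs and doubles as a
cross-check of the analytic path.

**Score model.**  Observed scores follow

    score(t) = E0_i + Kprog_i * t + Deff_i * Ce_i(t) + eps,
    eps ~ N(0, sigma_add^2),

i.e. an individual baseline, a linear natural-progression slope (the
placebo time course), and a drug effect linear in effect-site concentration.
The typical baseline depends on age through a power function normalised to
5 years: `E0 * (age/5)^beta_age` with `beta_age < 0` (younger children score
higher, largely because motor skills enter the composite below age 7).

## Variability model

`ke0`, `E0` and `Deff` carry log-normal inter-individual random effects;
`Kprog` carries an additive normal effect (its eta is on the score/day
scale, so negative individual slopes are admitted).  The `E0` and `Kprog`
etas are jointly normal with correlation `corr_e0_kprog` (default 0.48:
children with better baseline adaptive behavior also progress faster).
Residual error is additive on every observation including baseline — the
baseline is a fitted observation, not a covariate, which is why `E0` has
both a fixed effect and IIV.

Default variability values (`omega_ke0 0.21`, `omega_e0 0.20`,
`omega_deff 1.4`, `omega_kprog 0.018` score/day, correlation 0.48,
`sigma_add 1.6` points) are the final population estimates of the pediatric
analysis the package defaults reproduce.

## Default parameters and the PK placeholder

The PD defaults are published estimates.  The PK defaults are
**placeholders**: the adult estimates appear in a separate PK publication
and are not embedded here.  The placeholder set
(`cl_f 16000 L/day`, `v1_f 1600 L`, `q_f 6400 L/day`, `v2_f 3200 L`,
`d1 0.08 day` at 70 kg) preserves the published kinetic *shape* — absorption
over ~2 h, terminal half-life ~12 h, dose linearity — while the overall
concentration scale is chosen so that `Deff x Ce` is clinically sized: a
25-kg child on 7 g BID reaches a typical effect-site concentration of
~750 ug/L at week 12, i.e. a typical drug effect of ~1.6 points on top of a
~1.3-point placebo progression, matching the reported score-change regime
(treated medians ~1.7-3.7 points, placebo ~0.9-1.2, attainment 40-73%).
Absolute concentrations on this internal scale are not physiological serine
levels; anyone fitting real concentration data should substitute the
published adult PK estimates in `configs/params_default.yaml`.  All
calibration tests are simulate-then-recover, so their outcome does not
depend on the placeholder being "true".

## Synthetic trial generator

The generator emulates the phase-II design: `n = 145` children aged 2-11
years, 82.8% male, randomised ~1:1:1 to placebo / low / high arms
(largest-remainder allocation), weight-tiered full doses of 2/4/7/10/14 g
BID over bands [10,15)/[15,25)/[25,38)/[38,52)/[52,inf) kg (the printed
integer band labels are read as half-open intervals at the lower bounds),
half of those doses in the low arm, a two-week half-dose titration in the
high arm, dosing to day 168, placebo crossover to the high-dose regimen
(including titration) at day 84, and score observations at days
0/84/168/252 (day 252 is 12 weeks after the last dose).  Visits are at
exact nominal days; an optional missing-at-random per-visit dropout
probability (default 0) represents the handful of missed visits in the
real study; baseline is never dropped.

Age-weight-sex correlation comes from an embedded sex-by-age median-weight
table (ages 2-12, plausible growth-chart medians, linearly interpolated)
with log-normal spread of CV 15% truncated to 10-60 kg.  This reproduces
the monotone age-weight structure the simulations need (cohort median
weight ~21 kg, range ~10-60 kg) without claiming LMS growth-chart fidelity.
What the generator deliberately does **not** emulate: visit-window jitter,
informative dropout, adherence, baseline-severity-dependent randomisation.
Passing tests therefore demonstrate internal consistency of the method
under the stated design, not robustness to those real-data features.

## Estimation

The PD fixed effects (`ke0`, `E0`, `beta_age`, `Deff`, `Kprog`), the four
omega SDs with the single correlation, and `sigma_add` are estimated with
the PK fixed.  On the transformed scale (log for positive parameters,
identity for `Kprog` and covariate coefficients) the individual parameter
vector is Gaussian around a linear predictor `X_i theta`, which keeps the
M-step closed form.

**SAEM (primary).**  The E-step samples each subject's 4-dimensional eta
from its conditional posterior with three Metropolis-Hastings kernels
(prior independence, joint random walk, componentwise random walk; two
sweeps per iteration, two chains), vectorised across subjects — a single
model evaluation prices every subject's proposal at once, which is what
makes the estimator fast in pure numpy.  Chains start at the Laplace
conditional modes of the initial parameters, so early iterations sample
near the posterior instead of inflating the residual variance.  The M-step
is GLS for `theta`, moment matching projected onto the
diagonal-plus-one-correlation structure for Omega, and the stochastic-
approximation residual mean square for `sigma^2`.  Defaults: 300 burn-in
iterations (step 1, with variance moves tempered to at most ±5% per
iteration — a noisy single-draw variance estimate otherwise re-heats the
chains) and 100 smoothing iterations (step `1/k`).  After SAEM a
deterministic **polish** descends the Laplace objective from the SAEM end
point (L-BFGS on the transformed parameters), removing residual stochastic
drift; the reported optimum is then a stationary point of a deterministic
surface, which also makes the SAEM and Laplace routes agree by
construction.

**Laplace (deterministic route).**  Per-subject inner Newton on the etas
with analytic gradients and an exact Hessian (Gauss-Newton plus
second-order residual terms; only the `ke0` direction uses a finite
difference, taken on the effect-site curve in eta space), batched across
subjects with per-subject Levenberg damping.  The Laplace OFV
(-2 log marginal likelihood) is used for likelihood-ratio tests, for the
OFV reported after SAEM fits, and for standard errors via a central-
difference Fisher information matrix on the transformed scale
(delta-method back-transformed, RSE% = 100 SE/|estimate|).  On a 3-subject
toy with one random effect the Laplace OFV matches adaptive Gauss-Hermite
quadrature to <0.1 units (test suite).

**Degenerate cases.**  Etas with omega = 0 in the initial values are
structurally absent.  If any of the four core etas is absent the SAEM
M-step loses its linear structure, so `fit` switches to the deterministic
route; with no etas at all the problem collapses to nonlinear least
squares with the residual variance profiled out (this covers the
zero-noise recovery contract: noise-free data return the fixed effects to
>4 significant digits).

**Initial values.**  For user data, method of moments: `E0`, `beta_age`
and `omega_e0` from a log-log regression of baseline score on age;
`Kprog` from the mean placebo day-84 slope; exposure-side parameters start
at documented defaults (`ke0 0.01/day`, `Deff 0.001 L/ug`, `omega_deff 1`,
correlation 0) because raw scores carry little direct information about
them.  Correlation and omegas are bounded (|corr| <= 0.98, variances
floored at 1e-12) for numerical stability.

**Covariate search.**  Forward selection (default alpha 0.05) then
backward elimination (alpha 0.01) by likelihood-ratio tests with df = 1.
Continuous covariates enter as power functions normalised to the dataset
median (a log-ratio column in `X`); on the linear-scale `Kprog` the same
column acts as an additive shift per log covariate ratio, and sex enters
as a female indicator — conventions chosen to keep the M-step linear.  The
LRT clamps small negative OFV drops (optimizer noise, tolerance 0.5) and
raises on gross nesting violations.

**Bootstrap.**  Case bootstrap: subjects resampled with replacement,
each replicate refitted with the same options; medians and 2.5/97.5
percentiles are reported with the convergence count.

## Diagnostics

Goodness-of-fit records carry PRED (zero etas), IPRED (empirical-Bayes
modes from the Laplace inner optimisation) and IWRES = (obs - IPRED)/sigma
(flagged undefined at sigma = 0).  The prediction-corrected VPC simulates
replicate datasets under the original design (default 500), corrects
observed and simulated scores multiplicatively by the bin-median population
prediction (bins are the nominal visit days — observations are scheduled,
so no adaptive binning), and overlays observed 5/50/95 percentiles on the
2.5-97.5% envelopes of the simulated percentiles.  Plots are static files
rendered from the tables; tests assert on the tables.

## Dose-scenario engine

A 1000-child virtual population (ages 2-12, trial sex ratio) is split by
the candidate phase-III weight bands [10,14)/[14,21)/[21,35)/[35,50)/
[50,inf) kg and resampled to 200 subjects per band.  Each band is simulated
under placebo and under candidate BID doses (2-14 g) for 12 weeks (no
titration in scenario mode); the summary is the 5/50/95 percentiles of the
observed week-12 score change and the target attainment, the percentage
with an increase strictly greater than 2 points ("more than 2", so exactly
2 does not count).  Placebo and treated arms share etas and residual draws,
so dose contrasts are paired.  An optional parameter-uncertainty layer
redraws the fixed effects per population chunk from a normal on the
unconstrained scale with SD = reported RSE% — an approximation to
propagating estimation uncertainty.  `compare_fixed_vs_mgkg` doses the same
subjects (same etas *and* residuals) under the tiered fixed dose and under
200 mg/kg BID; `forest_ratios` reports per-bin median CL/F and E0 ratios
against a configurable reference bin (heaviest/oldest by default — the
natural reference is ambiguous, and the choice rescales all ratios by a
constant) with bootstrap 95% intervals.

The engine reproduces the *structure and direction* of the published
scenario table — treated > placebo attainment, monotone dose response,
band-wise mg/kg ranges — not its exact treated-arm cells, which depend on
the unpublished adult PK values.  Two systematic differences are expected
and documented: the placebo attainment implied by the published variability
parameters (~35-40%) exceeds the published table's placebo column, and the
placebo median change `Kprog*84 = 1.26` sits slightly above the printed
0.9-1.2 — the published simulation's resampling and uncertainty handling
are not fully specified, so the package reports what the stated parameters
imply.

## Numerical choices

- Closed-form kinetics are validated against stiff ODE integration at
  rtol 1e-6; `AUC = dose/CL` holds to 0.1% by quadrature.
- Removable poles at `ke0 = lambda_i` are handled by a relative-tolerance
  nudge; `expm1` is used where cancellation threatens.
- Laplace inner Newton: eta clipped to ±30 (overflow guard far outside any
  plausible posterior), Levenberg damping adapted per subject, eigenvalue
  floors only for step computation; the log-determinant uses the exact
  Hessian at the mode.
- Seeds: every stochastic routine takes an explicit seed (numpy
  `default_rng`); identical seeds give bit-identical outputs, and the CLI
  refuses to run stochastic stages without `--seed`.

## Problem sizes

Default test and reproduction sizes were chosen to keep each full
simulate-and-fit cycle at roughly 1-2 minutes on a single core: trials of
145 subjects (the study size), SAEM 300+100 iterations with 2 chains,
3 replicate trials in the reproduction script, 200 virtual subjects per
dose band, and 500 VPC replicates in the analysis scripts (reduced in the
unit tests).  Bootstraps in tests use a handful of replicates; the CLI
default is 200.

## Known limitations

- The absolute concentration scale is internal (see the PK placeholder
  note); `Deff` is only interpretable jointly with that scale.
- Single-trial estimates of `Deff` scatter widely (the published RSE is
  37.5%), which is why the reproduction script reports the median of three
  replicate experiments.
- `omega_ke0` is weakly identified by four visits per subject and tends to
  be estimated above its generating value while remaining inside the
  published interval; the fixed effects are unaffected.
- The Laplace approximation (4 observations, 4 etas per subject) is the
  package's likelihood authority for OFV comparisons; small absolute
  offsets from the exact marginal likelihood cancel in nested-model
  differences but are not zero.
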