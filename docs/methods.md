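# Methods

## Model

The observation model is a two-part (hurdle) model for a semicontinuous
repeated-measures outcome `y_ij ≥ 0` (energy intake in kcal in the interval
following prompt `i` of person `j`):

* `P(y_ij = 0) = π_ij = logit⁻¹(η0_ij)` — the zero part models the log-odds
  of **no** eating. This sign convention runs through the whole package:
  a positive zero-part coefficient means *more* skipping, and all
  interpretation helpers honour it.
* `y_ij | y_ij > 0 ~ Gamma(α, rate = α/μ_ij)` with `μ_ij = exp(η1_ij)` —
  the shape–mean parameterization, chosen so `exp` of the gamma-part linear
  predictor is directly the conditional mean in kcal. The conditional
  variance is `μ²/α` and the coefficient of variation `1/√α`.

The linear predictors contain fixed effects plus person-level random
intercepts and, optionally, person-level slopes of momentary (Level-1)
covariates. All random effects are jointly multivariate normal with
covariance `Σ = diag(σ) R diag(σ)`; the correlations of `R` linking the two
parts are the cross-part correlations. With one random slope per part the
model has 4 random effects and `R` contains 6 distinct correlations.
Setting `cross_part_correlated=False` zeroes the off-block of `R`
(equivalent to fitting the two parts with independent random effects).

Level-1 dispersion of the positive part lives entirely in the gamma shape
`α`; there is no additive residual on the log scale. `α` is a free
parameter with its own prior and posterior.

Conditional (subject-specific) quantities are interpreted throughout;
population-averaged means integrating over the random effects are not
produced. A consequence worth knowing: the back-transformed gamma intercept
`exp(β10)` understates the marginal mean of positive values by the factor
`exp(σ_u1²/2)` (≈1% at σ_u1 = 0.14); the reporting deliberately matches the
conditional interpretation.

## Priors

All priors are weakly informative and centred at zero:

| block | prior | rationale |
|---|---|---|
| intercepts | Student-t(3, 0, 5) | heavy-tailed, covers logit/log-kcal scales |
| slopes | Student-t(3, 0, 2.5) | heavy-tailed, scale 2.5 on the link scale |
| random-effect SDs | half-Student-t(3, 0, 2.5) | standard weak scale prior |
| gamma shape α | half-Student-t(3, 0, 2.5) | weak; posterior is data-dominated |
| correlations | independent uniform canonical partial correlations | see below |

The correlation matrix is parameterized by its Cholesky factor built from
canonical partial correlations (CPCs), each given a uniform prior on
(−1, 1) via a tanh transform. With two random effects (the intercept-only
model) this is exactly a uniform marginal on ρ; with more random effects
the marginals are near-uniform. The CPC parameterization guarantees positive
definiteness for any unconstrained value and makes the transform Jacobian a
closed form.

## Sampling

The sampler is a No-U-Turn sampler (recursive doubling, slice acceptance,
divergence threshold 1000 on the energy error) with:

* analytic gradients of the unconstrained joint log posterior (verified
  against finite differences in the test suite);
* non-centered random effects `u_j = diag(σ) L z_j`, `z_j ~ N(0, I)`, which
  removes the funnel between `σ` and `u` at small group counts;
* log transforms for `σ` and `α`, tanh for CPCs (Jacobians included);
* dual-averaging step-size adaptation (target acceptance 0.8) and diagonal
  mass-matrix estimation in doubling warmup windows (15% initial and 10%
  terminal step-size-only buffers);
* one master seed fanned out deterministically to per-chain generators, so
  identical seeds give bit-identical draws.

Defaults are 4 chains × 2000 iterations, first half warmup. Initial values
are moment-based (data logit of the zero share, log of the mean positive
value) with small jitter. Convergence is assessed by the split-chain
potential scale reduction factor (each chain halved; between/within variance
ratio). Rhat is undefined (NaN, with a warning) when the within-chain
variance is zero rather than silently 1. An effective-sample-size estimate
(Geyer initial positive monotone sequence) is reported but not gated on.
Nonconvergence produces a warning advising more iterations; chain failures
raise with the same guidance.

A conjugate reduction (exponential likelihood, gamma prior) is used in the
tests as an analytic oracle for the sampler, and the split-Rhat
implementation is cross-checked against an independent library
implementation.

## Pre-processing

* **Intake-to-prompt matching.** Event-contingent kcal records are summed
  into the half-open window `(t, min(t_next, t+2h)]` after each prompt at
  `t`; the final prompt of a day gets `(t, t+2h]`. Half-open boundaries mean
  an event exactly at a prompt time belongs to the *preceding* window, so no
  event is counted twice; events after the last window of a day are
  discarded. Missed prompts are simply absent rows — the 2-hour cap already
  bounds the resulting long gaps. The cap is configurable (`cap_hours`).
* **Zeros are exact.** An interval counts as "no eating" only when the
  matched total is exactly 0 kcal; no epsilon thresholding.
* **Person-mean centering** subtracts each participant's own mean from a
  Level-1 covariate (missing values ignored in the mean, preserved in the
  output), so its coefficient reflects within-person fluctuation.
  Centering is idempotent.

## Synthetic-data generator

`simulate_dataset` draws from exactly the fitted model: per person a
correlated random-effect vector (non-centered, so zero SDs are handled
exactly), per prompt a Bernoulli no-eating indicator and, when eating, a
gamma amount. Defaults emulate a three-day signal-contingent EMA protocol:

* 99 participants × 8 semi-random prompts/day × 3 days (prompts jittered on
  a grid over 08:00–22:00), 14% of prompts missed completely at random,
  leaving ≈ 2040 intervals;
* intercept-only truth at the reference estimates β00 = −0.06, β10 = 6.1,
  σ_u0 = 0.23, σ_u1 = 0.14, ρ = 0.77 — implying ≈ 48% zero intervals and a
  mean positive intake of ≈ 446 kcal;
* gamma shape α = 2 (CV ≈ 0.71), a free dispersion knob chosen to give
  realistic right skew; no reference estimate exists for it, so tests check
  recovery of α rather than a target value;
* a binary Level-2 covariate with prevalence 0.5 (mimicking gender) and a
  standard-normal, person-mean-centered Level-1 covariate (mimicking
  momentary energetic arousal).

What the generator does **not** emulate: informative missingness (real
skipped prompts correlate with behaviour), measurement error in
self-reported intake, diurnal and day-of-study structure in eating
probability, and digit preference in kcal totals. Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

## Parameter recovery

`recovery_study` repeats simulate → fit → summarize, recording posterior
means, 95%-CI coverage of the truth, bias with its Monte Carlo SE, and
RMSE. Replicates whose worst split-Rhat exceeds 1.05 are counted, never
dropped. The test suite runs 20 replicates at a reduced design
(30 participants, 2 chains × 800 iterations) to keep the default run fast;
coverage is checked against [80%, 100%] (binomial noise at 20 replicates).

A known and expected behaviour at that reduced design: the posterior mean
of the cross-part correlation shrinks markedly toward 0 (and SD posterior
means sit slightly above small truths). With ~20 observations per person
the person-level zero-part effects are weakly identified, so the posterior
on ρ is wide and its mean is pulled toward the prior centre. This is a
property of Bayesian point estimation for bounded, weakly identified
parameters — interval coverage remains nominal — and it disappears as the
number of participants and prompts grows.

## Numerical choices

* `log(1±logit⁻¹)` terms use softplus/`logaddexp`; the CPC prior uses an
  overflow-safe `log cosh`.
* Divergent or non-finite trajectories are rejected within the NUTS tree;
  transient overflow during warmup exploration is silenced locally.
* Gradient of the correlation Cholesky is computed by reverse-mode
  accumulation through the CPC recursion (exact, no finite differences).
* Equal-tailed credible intervals are 2.5/97.5 percentiles; reports use the
  conventional z = 1.96 for population ranges (the exact 97.5% quantile
  1.959964 is available via `compat_z=False`; the difference is < 0.01%).
* Display rounding: 2 decimals for kcal and correlations, 3 for
  probabilities.

## Sizes used by the default test run

Chosen as the package's own balance of fidelity and turnaround: one
full-budget intercept-only fit at the study scale (99 × 24, 4 × 2000), a
20-replicate recovery study at 30 participants (2 × 800), and small
datasets elsewhere. The full suite completes in roughly ten minutes on one
CPU core.

## Known limitations

* The sampler is single-machine, pure Python/numpy; very large designs
  (thousands of participants) will be slow.
* No probit zero part, log-normal/log-skew-normal positive part,
  cross-level interactions, or model-comparison criteria.
* Priors are fixed at the weakly informative defaults above; there is no
  interface for informative prior elicitation.
* `describe` and the load report treat missing outcomes as ignorable;
  informative missingness must be handled upstream.
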