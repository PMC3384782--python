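# Methods

## The model

`jointlgm` fits joint models for a repeatedly measured 0–100 symptom score
and a right-censored time to disease progression, in the setting of a
two-arm oncology trial with 21-day treatment cycles (0.7 month).

**Longitudinal sub-model.** The per-cycle mean score of subject *i* at time
*t<sub>ij</sub>* (months since randomization) is

    Y_ij = eta_i(t_ij) + eps_ij,        eps_ij ~ N(0, sigma^2)
    eta_i(t) = f(t)' b_i,               f(t) = (1, t) or (1, t, t^2)
    b_i = beta X_i + zeta_i,            zeta_i ~ N_r(0, Sigma)

so each subject follows its own linear or quadratic latent trajectory with
population means driven by baseline covariates.  Five named specifications
control where treatment enters: `l_i`, `l_s`, `l_is` (linear; treatment on
intercept, slope, or both) and `q_s`, `q_sq` (quadratic; treatment on
slope, or slope and curvature).  Entries of `beta` outside a
specification's inclusion map are structural zeros that the parameter
packing never exposes to the optimizer.  An extended specification admits
arbitrary binary baseline covariates in every sub-model, except that
post-baseline interventions (treatment, supplementation) are excluded from
the intercept sub-model, because the intercept is pre-treatment status.

**Survival sub-model and links.** The hazard of progression is
proportional-hazards with a piecewise-constant baseline, and depends on the
latent growth through one of two links:

* *shared random effects* (`rem` prefix):
  `log h_i(t) = log h_0(t) + X_si' alpha + b_i' gamma`, with one link
  coefficient per growth coefficient;
* *stepwise latent trajectory* (`traj` prefix): time is split on a grid
  (default `t_k = 0.7k`, k = 1..7, the cycle boundaries, with the last
  interval open-ended), a per-interval survival variable
  `T_ik` and indicator `delta_ik` are carved out of `(T_i, delta_i)`, and
  within interval *k* the hazard multiplier is frozen at the trajectory
  value at the left endpoint, `gamma * eta_i(t_{k-1})`.  Refining the grid
  recovers the continuous-time link `gamma * eta_i(t)`; a test verifies
  monotone convergence of the density as the step shrinks 0.7 → 0.007.

Censoring codes follow the trial convention throughout: `censored = 1`,
event = 0.  A boundary time falling exactly on a grid point is assigned to
the lower interval and the zero-length spillover is suppressed, since a
zero-exposure interval would contribute a degenerate hazard factor.

**Likelihood.** The marginal log-likelihood integrates `b_i` out of
(survival density × measurement Gaussians × random-effect prior)
subject by subject.  The survival factor is log-concave in `b_i` under
both links, so the integrand's mode is found by a damped Newton iteration
with analytic gradient and Hessian, started at the closed-form Gaussian
posterior mode of the longitudinal part; adaptive Gauss–Hermite quadrature
(default 9 nodes per dimension) is centred and scaled there.  This makes
the rule exact whenever the integrand is Gaussian — in particular at
`gamma = 0`, where a test checks equality with the closed-form factorized
likelihood to 1e-6.  All per-subject quantities are evaluated as batched
array operations, so one likelihood evaluation at n ≈ 450 costs tens of
milliseconds.

## Estimation and inference

* Unconstrained parameterization: free `beta` entries natural;
  `Sigma` via its log-Cholesky factor; `sigma` and baseline heights on the
  log scale; `alpha`, `gamma` natural.
* Starting values: two-stage per-subject least squares plus moments for
  the growth side; a Breslow Cox fit for `alpha`; occurrence/exposure
  rates for the baseline; `gamma = 0`.
* Optimizer: BFGS with finite-difference gradients (robustness over speed
  at desk scale).  The achievable gradient norm is bounded by
  finite-difference noise, which grows with |log L|; the convergence flag
  therefore accepts a gradient max-norm below `1e-4 (1 + |log L|)` in
  addition to the optimizer's own success flag.  Log hazard multipliers
  are capped at 50 (hazard ratio e^50) purely to keep the arithmetic
  well-conditioned while the optimizer transits absurd regions; no
  plausible fit approaches the cap.
* Standard errors: numerically differentiated observed information at the
  estimate, inverted (pseudo-inverse with a warning if not positive
  definite).  The choice of observed information is a design decision; the
  reference analyses do not state their method.
* `BIC = -2 log L + p log n` with `n` the number of subjects (the
  likelihood is subject-indexed) and `p` the number of free parameters
  including baseline heights.  Model comparisons attach Raftery evidence
  grades (0–2 weak, 2–6 positive, 6–10 strong, >10 very strong) and
  refuse to compare fits whose data checksums differ.
* The joint null "no link" (`gamma = 0` in every component) is tested by a
  Wald chi-square on the fitted `gamma` block.
* Baseline-hazard breakpoints default to the cycle grid (8 heights);
  unique event times are available via `baseline_grid="events"` for a
  nonparametric flavour, at a substantial cost in dimension for the
  numeric-gradient optimizer.

**Effect decomposition.** Under the shared random-effects link the log
hazard is linear in `b_i`, so a covariate's overall log-hazard effect
splits exactly into a direct part (`alpha_c`) and indirect parts
`gamma_m * beta_{m,c}` through each growth coefficient whose sub-model
contains it — for treatment under `q_s`, `alpha + gamma_1 beta_11`.
Overall-effect standard errors use the delta method on the joint
covariance of `(alpha, gamma, beta)`; a parametric bootstrap is a
documented alternative but not implemented.

## Comparator analyses

* **MMRM**: Gaussian ML with saturated arm × cycle cell means and a CS or
  AR(1) within-subject covariance (profiled GLS mean, Nelder–Mead over
  variance and correlation).  ML rather than REML so BICs are comparable
  across mean structures; the BIC penalty uses the subject count.
  LSMeans are the model-implied cell means; arm differences use
  delta-method SEs.
* **Cox models**: Breslow tie handling on counting-process episodes, by
  damped Newton on the partial likelihood with analytic derivatives.
  The naive time-varying model carries the last observed cycle mean
  forward (LOCF) and enters subjects at their first assessment (delayed
  entry) rather than imputing a pre-assessment value; subjects with no
  assessment before their observed time are dropped with a logged count.

## The synthetic-trial generator

The trial the analysis was designed for is proprietary, so the generator
reproduces its design: ~1:1 allocation (n = 448 by default), 21-day
cycles, assessments on days 8, 15, 19 of each cycle (the first two
jittered ±1 day, per protocol), scores truncated at the observed survival
time and at cycle 6, and administrative censoring.  Default parameters are
the published shared random-effects estimates for the five-item average
symptom burden index (ASBI5): growth means (27.9, 3.23 − 1.17·Z, −0.35),
link coefficients (0.024, 0.105, 0.414), direct treatment hazard ratio
0.71.  Quantities the published tables do not report were fixed once at
realistic values for a 0–100 scale:

| parameter | value | rationale |
|---|---|---|
| random-effect SDs | (15, 2, 0.6) | intercept spread comparable to the score scale; slope/curvature spreads a fraction of their means |
| measurement error SD | 7 per assessment | cycle means of 3 assessments then have SD ≈ 4 |
| baseline hazard | 0.075 /month, constant | control-arm median progression ≈ 4 months, matching the reported 3.9 |
| censoring window | Uniform(5, 15) months | gives ≈ 25–30% censoring; the true censoring mechanism is unreported, so this is an arbitrary, documented choice |
| days per month | 30 | makes the 21-day cycle exactly 0.7 month; exposed in the configuration |

Scores are clipped to [0, 100] with a per-row flag (the Gaussian model is
the analysis assumption; clipping is a realism knob that tests can
exclude).  One global seed spawns per-subject substreams, so a subject's
realization is invariant to enlarging the trial (given the same arm
assignment).  Event times come from inverse-transform sampling of the
subject's full hazard, which is piecewise-constant under both links, so
the inversion is closed-form and exact.

What the generator does **not** emulate: correlated multi-item batteries
(items are one-at-a-time, as in the reference analyses), dropout
mechanisms beyond event/censoring truncation, skewness or zero-inflation
of real symptom scores, and post-progression assessments.  Passing
recovery tests therefore demonstrate internal consistency of the estimator
under the stated model, not robustness to those real-data features.

## Problem sizes in the test suite

Simulation-based checks are sized to run comfortably on one desk CPU:
single-cohort parameter recovery at the published trial size (n = 448, one
seed, 5 quadrature nodes); mean-bias over 10 seeds at n = 150; BIC model
selection (q_s vs l_s) over 10 seeds at n = 448; naive-vs-joint
attenuation over 20 replications at n = 120 with measurement-error SD 30
(cycle-mean reliability ≈ 0.4, so the attenuation is pronounced).  The
10-seed mean-bias study uses a smaller n than the single-cohort check
because it multiplies the fit cost tenfold; its Monte-Carlo SE is computed
from the seed-to-seed spread.

## Numerical choices and edge cases

* Quadrature nodes: 9 per dimension by default; a convergence test checks
  that 9 → 15 changes the log-likelihood by < 1e-6 on a fixture.  Fits in
  the test suite use 5 nodes, which the same convergence ladder justifies.
* `Sigma` must be symmetric positive definite; the zero matrix is accepted
  only with an explicit flag (noise-free simulation mode).  Rejection
  messages name the offending eigenvalue.
* Monotone Cox partial likelihoods (all events in one arm) are flagged and
  the coefficient capped at ±15 with a warning.
* Ties: Breslow everywhere; simulated continuous times essentially never
  tie.  An assessment falling exactly at the observed survival time is
  retained in preprocessing (a measurement "at" progression precedes the
  event administratively) but contributes no exposure to the episode
  table.
* The published Gaussian kernels are read as standard normal densities;
  any consistent normalizing constant cancels from all BIC comparisons.

## Known limitations

* The trajectory-link decomposition into direct/indirect effects is not
  defined (the hazard depends on the trajectory value, not separably on
  the coefficients); decomposition requires the shared random-effects
  link.
* Finite-difference gradients limit the final gradient norm; estimates are
  stable (refitting from a fit moves the log-likelihood by < 1e-8) but
  extremely flat likelihoods at small n can terminate with a conservative
  `converged = False` flag.
* The event-time baseline grid is supported but impractically slow for
  routine fitting with numeric gradients; the cycle grid is the default.
* No REML, no profile-likelihood or bootstrap intervals, no Bayesian
  machinery, no latent-class or spline extensions.
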