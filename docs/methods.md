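# Methods

## Model

Regional gray-matter volumes, rescaled per region to [0,100], are the
states of a linear time-invariant system

    dx/dt = A x + C u(t),        y = x(t_scan) + X₀ b₀ + e,

integrated by forward Euler with Δt = 0.1 years from a configurable onset
age (default 6 y; model time zero is anchored there, and the onset can be
swept over 3–9 y in model comparison).  `A` (1/years) carries negative
self-connections — each a_ii is an exponential decay rate with the
interpretable decay time t(L) = (1/a_ii)·ln(1−L/100) — and, optionally,
symmetric between-region couplings restricted to a-priori subnetworks and
sign-constrained (only positive or only negative).  `C` (volume units per
year per unit input) holds regional sensitivities.  Confounds X₀
(mean-centred TICV and one-hot site indicators, first site as reference)
enter the observation model with free coefficients b₀ rather than being
pre-regressed.  Observation noise is independent Gaussian per region with
a free log-precision per region; this is the minimal variance structure
consistent with the observation model, and it is also exactly what the
synthetic generator produces.

### Inputs

* **Puberty (manifest).** A sigmoid pubertal transition
  h(t) = 1/(1+10^((p1−t)p2)) is fitted to rescaled questionnaire scores
  (raw 1–4 stage means mapped by (m−1)/3) by multi-start nonlinear least
  squares (starts p1 ∈ {10,12,14,16}, p2 ∈ {0.1,0.3}; asymptotic 95% CIs
  from the Jacobian).  The input is the analytic derivative
  u₁ = ln(10)·p2·h·(1−h), maximal at p1 with value ln(10)·p2/4 and unit
  integral over a wide window.  Default group-level parameters (girls
  p1 = 12.66, p2 = 0.21; boys p1 = 14.34, p2 = 0.22) come from published
  fits to a large pediatric cohort and can be overridden per group.
* **Alpha growth (latent).** A critically damped second-order system,
  dv/dt = −(2/τ)v − u/τ² + (20/τ)δ, du/dt = v, with u(0) = 1, v(0) = 0 at
  onset.  The delta impulse is realised as an instantaneous increment of
  v by 20/τ at the onset grid point; with the stated initial conditions
  this yields the closed form u(t) = e^(−t/τ)(1 + 21 t/τ), which peaks at
  (20/21)τ after onset and is used as the integration oracle in tests.
  The printed form of the impulse weight and initial condition are stated
  without reconciliation in the source description; the jump-plus-initial
  condition reading was chosen because it reproduces a standard
  alpha-function shape with a single latency parameter.
* **Gaussian growth (latent, parametric).** u₂(t) = exp(−(t−m_g)²/(2σ²))
  with one free mean per group and one shared spread.  The squared
  deviation is used although one printed formula omits the square — the
  function is explicitly described as having the shape of a Gaussian
  density, so the missing square is treated as a typo.

At most one latent growth input is active per model.  Group structure
(e.g. gender) is expressed per parameter block: x0, A, C and the latency
can each be shared or group-specific; confound coefficients are always
shared.

## Inversion

The posterior over the unconstrained parameter vector is Gaussian
(Laplace assumption) and optimised by Gauss–Newton ascent on the free
energy

    F = E_q[log p(y|θ)] − KL(q(θ)‖p(θ)) − KL(q(λ)‖p(λ)),

with the expected log-likelihood including the trace correction
tr(JΣJᵀ).  Constraints are enforced by transforms: negative-constrained
entries are −exp(λ), positive ones +exp(λ); symmetric couplings are a
single free parameter mirrored across the diagonal.  Jacobians are
central finite differences with relative step 1e-4, evaluated as one
vectorised batch integration.  Per-region noise log-precisions are
updated by Newton steps inside each outer iteration (closed-form gradient
and curvature), with posterior variances from the curvature entering a
noise-hyperparameter KL term.  A Levenberg–Marquardt damping schedule
accepts a step only if it increases F relative to the best estimate so
far (a diverged trial step counts as a rejection), so the reported
iteration trace is non-decreasing by construction.  Convergence is
declared when an accepted step improves F by less than 1e-3 nats
(default; 128 iterations maximum, best iterate returned and flagged if
not converged).

For a model that is linear in its parameters (the cubic reference model)
with fixed noise, the Laplace assumptions hold exactly and F equals the
log marginal likelihood; the test suite verifies agreement with the
conjugate closed form to ~1e-10 relative error.

### Priors

The unconstrained-space defaults (all overridable via `PriorSpec`):
self-connections λ ~ N(ln 0.01, 1); couplings λ ~ N(ln 0.001, 1)
(identity scale N(0, 1e-4) when unconstrained); sensitivities N(0, 1);
τ = exp(λ), λ ~ N(ln 2, 0.25); Gaussian-growth mean N(onset+2, 4) with
σ = exp(λ), λ ~ N(ln 2, 0.25); initial states N(m, 25) with m the
per-ROI mean of the earliest-age tertile of scans; confound coefficients
N(0, 100); noise log-precision hyperprior N(0, 16).  Cubic coefficients
have order-dependent variances (25, 4, 0.25, 0.01) so that each term's
prior contribution over a 16-year window is comparable.

### Model comparison

Free energies of models fitted to the identical data table (verified by a
data fingerprint) are compared as log Bayes factors; posterior model
probabilities are the softmax of F under a uniform model prior; ties are
broken by the lower free-parameter count.  This is fixed-effects
comparison — one model per dataset; subject-level random-effects
comparison is out of scope.  Fit quality is reported as per-region RMSE
per group, and residual variances of two model classes are compared by a
two-sided two-sample F test.

## Synthetic cohorts

`make_default_truth` defines the study scenarios (no input, puberty only,
alpha only, Gaussian only, puberty+alpha, within- and between-subnetwork
coupling).  Defaults: self-connections spanning −0.030…−0.005 /y for the
first group (covering the interpretable exemplars −0.005 and −0.02) with
the second group scaled by 0.6 (a detectable gender difference in decay
rates at the reference sample size — chosen by a pilot power analysis on
seeds disjoint from all test seeds, since an arbitrary smaller difference
would make the sharing comparison uninformative by design); an
anterior-to-posterior gradient of alpha sensitivities (0.6 → 0.1);
puberty sensitivity 2.0 concentrated in the last two regions (the
hippocampus–amygdala analogue; a small, spatially localised effect,
compatible with the N(0,1) sensitivity prior); latencies τ = 2 y (girls)
vs 3 y (boys); Gaussian-growth means 7 vs 8 y with σ = 2 (generic
plausible values — the cohort-level fitted means reported for the real
data are deliberately not baked in); symmetric negative couplings −0.006,
the strongest value comfortably inside the stability envelope.  All
scenarios are verified stable (negative spectral abscissa, Euler-stable
at Δt = 0.1).

`generate_cohort` emulates the reference repeated-measures design:
subjects enter uniformly over 6–19 y with 2 or 3 annual scans (a Bernoulli
mix, or an exact allocation when a target scan count such as 637 is
requested), six sites with additive offsets, log-normal TICV (sd 5 % on
the log scale) with a weak age trend and a small per-region coefficient,
and i.i.d. Gaussian noise of sd 2 per region on the [0,100] scale.  A
fixed seed reproduces the table byte for byte.

What the generator does *not* emulate: subject-level random effects
(every subject in a group follows the group trajectory), shared residual
covariance across regions, missing data, and scanner drift.  Passing
recovery tests therefore demonstrate correctness of the estimation and
comparison machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Test problem sizes

Parameter recovery uses 8 regions, 200 subjects (2–3 scans each) and 20
replicates, pooling coverage of the 95 % posterior intervals over all
free parameters.  The model-comparison recoveries (input structure,
coupling topology, group sharing) run at the reference sample size of
151+135 subjects and exactly 637 scans.  Fits take well under a second
each at these sizes because the finite-difference Jacobian is evaluated
as a single batched Euler sweep.

## Known limitations

* **Coupling topology is empirically non-identifiable at group level in
  this regime.**  Over a 6–22-year window with |a_ii|·T ≤ 0.5, the
  coupled drive a_ik·x_k(t) from smooth, slowly varying partner
  trajectories is absorbed almost exactly by each region's own free
  decay rate, initial state and input sensitivities: fitting the
  uncoupled model to noise-free within-coupled data (637 scans, the
  strongest stable couplings) leaves a maximal RMSE of ~0.005 on the
  [0,100] scale — vastly below any realistic noise level, so no feasible
  sample discriminates the four coupling topologies.  The corresponding
  recovery test documents this: evidence differences between topologies
  on synthetic data are at noise level.  Evidence differences reported on
  real data plausibly reflect structure outside the fitted model class
  (e.g. shared residual covariance), which the generator deliberately
  omits.
* Observation sampling uses the nearest grid point (maximal age error
  0.05 y at Δt = 0.1), not interpolation.
* States are not constrained non-negative; with negative self-connections
  and the default priors fitted trajectories stay in range, and hard
  constraints would break the Laplace assumptions.
* Nonlinear observation models, cortical-thickness/surface features and
  stochastic state noise are out of scope.
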