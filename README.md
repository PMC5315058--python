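# structdyn

Multivariate dynamical-systems modelling of longitudinal structural brain
change: regional gray-matter volumes are treated as states of a linear
dynamical system driven by developmental growth factors, inverted with a
variational Laplace (free-energy) scheme, and compared against
alternatives by Bayesian model evidence.

The package is aimed at researchers analysing repeated-measures
morphometry (2–3 scans per subject at irregular ages) who want a
*generative* account of concerted regional change — decay rates, growth
inputs, regional sensitivities, inter-regional coupling — rather than
independent per-region curve fits.

## The model

For D regions of interest, the rescaled volumes x evolve as

    dx_i/dt = Σ_k a_ik x_k + Σ_j c_ij u_j(t)

where `A = (a_ik)` holds self-connections (negative ⇒ exponential decay)
and optional symmetric between-region couplings, and `c_ij` is region i's
sensitivity to input j.  Two inputs are supported:

* **puberty** (manifest): u₁ = dh/dt, the derivative of a sigmoid pubertal
  transition h(t) = 1/(1+10^((p1−t)·p2)) fitted to questionnaire scores —
  maximal at the age of fastest pubertal change p1;
* **latent growth**: either an alpha function (critically damped
  second-order system, u₂(t) = e^(−t/τ)(1+21t/τ), one latency τ per
  group) or a Gaussian impulse exp(−(t−m_g)²/2σ²).

The system is integrated by forward Euler (Δt = 0.1 y) from a
configurable onset age; observations are the states at each scan age plus
linear confounds (TICV, site indicators) and i.i.d. Gaussian noise per
region.  A per-region cubic polynomial serves as the conventional
reference model.  The self-connection a_ii maps to an interpretable decay
time t(L) = (1/a_ii)·ln(1−L/100): a region with a_ii = −0.005 /y loses
10 % of its volume in ~21 years, one with −0.02 /y in ~5.3 years.

Inversion uses variational Laplace: Gauss–Newton ascent on the free
energy F (accuracy − complexity), with Levenberg–Marquardt damping,
per-region noise log-precisions updated in an inner loop, and sign
constraints imposed through log transforms.  Differences in F between
models fitted to the same table are log Bayes factors.

A synthetic-cohort generator (`structdyn.synthetic`) produces
longitudinal tables with the full design — two gender groups, 2–3 annual
scans at irregular entry ages, six sites with offsets, a TICV confound,
observation noise — from known ground-truth parameters, so the whole
pipeline is testable end to end.

## Worked example

Simulate a cohort from the puberty+alpha scenario and fit the generating
model:

```python
import structdyn as sd

truth = sd.make_default_truth(D=8, scenario="puberty_plus_alpha")
design = sd.CohortDesign(n_subjects=(100, 100), seed=1,
                         sites=("s1",), site_offsets=(0.0,), ticv_coef=0.0)
cohort, truth = sd.generate_cohort(design, truth)
post = sd.variational_laplace(truth.spec, cohort)
```

This prints (via the summary lines in the example script):

```
free energy: -7690.1 nats (9 iterations, converged=True)
tau girls: 1.95 y (truth 2.0), tau boys: 2.93 y (truth 3.0)
a_roi_01[F]: -0.0294 /y (truth -0.0300)
10% loss time for that rate: 3.6 y
per-ROI RMSE: [2.01 1.92 2.07 2.01 1.98 2.07 2.   2.03]
```

The group-specific growth latencies (girls earlier than boys) and the
regional decay rates are recovered from 460 noisy scans, and the
residual RMSE matches the generating noise sd of 2 on the [0,100] volume
scale.

The same analysis from the shell, ranking candidate input structures by
model evidence:

```
$ structdyn simulate --rois 8 --scenario puberty_plus_alpha \
      --n-subjects 60,60 --seed 11 -o sim
wrote 283 scans to sim/cohort.csv
$ structdyn compare -c sim/cohort.csv -m models.yaml -o cmp
         model  free_energy  log_bf_vs_best  probability
 puberty+alpha -5141.214618         0.00000          1.0
       puberty -6287.737937     -1146.52332          0.0
intrinsic_only -6572.882268     -1431.66765          0.0
best model: puberty+alpha
```

where `models.yaml` lists the candidate `model:` dictionaries (inputs,
coupling, group sharing, priors).  `structdyn fit` writes a posterior
parameter table and per-region RMSE; `structdyn report` exports the
fitted group trajectories as plain CSV.

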