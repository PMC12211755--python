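# Methods

This note records the model, the simulation conditions, the numerical
choices, and the limitations of the `adaptcrt` simulation engine.

## Data-generating mechanism

Trials are four-arm cluster-randomised designs with a binary outcome
(1 = favourable). For participant *i* in cluster *m* of arm *j*:

- `Y_imj ~ Bernoulli(p_mj)` with
  `logit(p_mj) = beta_0 + X_mj beta_j + alpha_m`;
- `alpha_m ~ N(0, sigma_a)` with
  `sigma_a = sqrt(ICC * (pi^2/3) / (1 - ICC))`, the latent-variable
  parameterisation of the intra-class correlation for a logistic model
  (residual variance `pi^2/3`);
- scenario probabilities map to coefficients on the **conditional**
  (cluster-specific) scale: `beta_0 = logit(p_1)` and
  `beta_j = logit(p_{j+1}) - logit(p_1)` exactly, with no marginal
  calibration. Consequently the *marginal* event proportion at ICC > 0
  is biased upward for p < 0.5 (Jensen effect); the bias is shared
  equally by all arms, so its effect on comparative operating
  characteristics is minimal. This is a deliberate design choice, not
  an accident, and is covered by a direction test.

Scenarios (per-arm event probabilities, control first):

| scenario | probabilities | meaning |
|---|---|---|
| 1 | 0.1, 0.2, 0.4, 0.6 | clearer optimal arm |
| 2 | 0.1, 0.3, 0.4, 0.5 | less clear optimal arm |
| 3 | 0.1, 0.1, 0.1, 0.1 | null (type-1 error) |

The factorial design space crosses these with ICC ∈ {0.05, 0.1, 0.2},
participants per cluster n ∈ {5, 25, 50}, clusters per arm
k ∈ {5, 10}, and adaptive vs fixed — 108 cells. Clusters are enrolled
whole, round-robin across arms, so the trial is balanced at any interim
cut; cluster indices are globally unique and each new cluster draws a
fresh random intercept.

## Analysis model and sampler

Each dataset is analysed with the hierarchical Bayesian logistic model

```
Y ~ Bernoulli(inv_logit(theta_1 + W alpha + X_2 theta_2 + X_3 theta_3 + X_4 theta_4))
theta_1..theta_4 ~ N(0, 2)        alpha_m ~ N(0, sigma_a)
sigma_a ~ half-N(0, 0.2)
```

`theta_1` is the control log-odds (intercept); `theta_2..theta_4` are
contrasts vs control. Best-arm status in a posterior draw is the argmax
over arm-level predictors `theta_1` and `theta_1 + theta_j`, which is
the argmax over `(0, theta_2, theta_3, theta_4)`; the control can
therefore be "best", and ties (measure-zero) go to the lowest arm
index. Since all participants in a cluster share one linear predictor,
the likelihood is reduced to per-cluster binomial counts; a gradient
costs O(K) for K clusters.

Sampling is a No-U-Turn sampler written for this model (numba-compiled):

- dynamic trajectory doubling with slice sampling across the tree,
  iterative U-turn checks via a checkpoint stack (no recursion),
  divergence declared when the joint log-density falls 1000 below the
  initial point;
- dual-averaging step-size adaptation (gamma 0.05, t0 10, kappa 0.75)
  to a target acceptance of **0.99** (deliberately high: with 3–5
  clusters per arm the posterior has difficult geometry, and small
  steps buy robustness);
- windowed diagonal mass-matrix adaptation (75-iteration initial
  buffer, doubling windows from 25, 50-iteration terminal buffer,
  regularised sample variances), step size re-initialised at window
  boundaries;
- defaults: 4 chains × (750 warmup + 750 draws) = 3000 retained draws,
  maximum tree depth 10, uniform(-2, 2) initialisation on the
  unconstrained scale;
- cluster effects are **non-centered** (`alpha_m = sigma_a * z_m`,
  `z_m ~ N(0,1)`; the centered parameterisation is available via a
  flag) and `sigma_a` is sampled on the log scale with its Jacobian.

The sampler is validated three independent ways in the test suite:
prior-only sampling against closed-form prior moments; a full-posterior
comparison against an affine-invariant ensemble sampler run on the
*marginalised* model (cluster effects integrated out by 41-node
Gauss-Hermite quadrature — different parameterisation, different
algorithm); and frequentist interval calibration over 200 replicate
datasets.

On calibration: at ICC = 0 the central 90% posterior intervals for the
contrasts cover the generating values at ~92%. At ICC > 0 coverage
drops to ~84–85% because the half-N(0, 0.2) hyperprior is tight
relative to the true latent SD (0.416 at ICC 0.05; 0.907 at ICC 0.2)
and the N(0, 2) prior shrinks the largest contrast (2.60 in
scenario 1). That prior-data conflict is part of the analysis model
being studied — the hyperprior is kept as specified (both scales are
configurable in `SamplerSettings`) — so the calibration test runs at
the ICC = 0 cell, where it isolates likelihood/sampler correctness from
the deliberate prior choice.

Convergence screening follows the usual Stan-style workflow via arviz:
rank-normalised split R-hat and bulk/tail ESS, computed for
`theta_1..theta_4` and `sigma_a`. A fit is **flagged** when any
treatment-arm parameter (`theta_2..theta_4` only) has R-hat > 1.05 or
bulk/tail ESS < 400 (100 per chain). Diagnostics are not computed for
the individual cluster effects: they never enter the flag and per-
parameter calls would dominate runtime; their draws are retained. A fit
is *failed* (distinct from flagged) when draws are non-finite or more
than 25% of retained iterations diverge; it is retried once with fresh
sub-seeds and then recorded as an error on the trial result. Failed
fits count as non-successes in the denominator and are reported as a
separate failure proportion.

## Adaptive rules

One interim analysis, when `ceil(interim_fraction * k)` clusters per
arm are recruited (default fraction 0.5: at 3 of 5 or 5 of 10).
Precedence at the interim:

1. **Futility stop** if `P(best) < 0.3` for *all* of arms 2–4 (the
   control's probability is ignored). If both rules fire, futility
   wins and the trial stops; a stopped trial cannot be a success.
2. **Arm drop** (at most one per interim): among arms 2–4 with
   `P(best) < 0.05`, drop the one with the lowest probability, ties
   broken by the lowest posterior-mean contrast. The control is never
   dropped.
3. Otherwise continue with all arms.

After a drop (or continue), the unspent budget `4k − 4·interim` is
split as evenly as possible over the remaining arms, with any remainder
assigned to arms drawn uniformly without replacement. The final model
is fitted on **all** accumulated data, including the dropped arm's
interim clusters (its contrast remains estimable, so the success
criterion stays evaluable for every arm). Interim fits that are
convergence-flagged still produce decisions; the flag is recorded
separately.

Success: non-null scenarios require `P(arm 4 best) >= 0.95`; the null
scenario counts any treatment arm reaching 0.95 as an incorrect
success. No multiplicity adjustment is applied — the disjunction *is*
the type-1 definition.

## Monte Carlo machinery

- **Seeds.** One master seed; replicate *r* of grid cell *c* uses
  `SeedSequence(master, spawn_key=(c, r))`, split further into a
  data-generation stream and a sampler stream. Any replicate is
  reproducible in isolation and results are invariant to worker count
  and scheduling.
- **Repetition planning.** `required_repetitions(p, mcse)` =
  `ceil(p(1-p)/mcse^2)`; the worst case (p = 0.5) at a 1% Monte Carlo
  SE gives 2500 replicates per cell.
- **Aggregation.** Per cell: success proportion (power or type-1
  error) with binomial MCSE, decision frequencies (continue /
  drop-arm-2/3/4 / futility partition), convergence-flag and
  fit-failure proportions.
- **Problem sizes.** Full-scale studies (108 cells × 2500 replicates)
  are a cluster-compute job. The bundled checks run single design
  cells: the test suite uses 100–150 replicates per cell with 3-SE
  binomial tolerance bands, and `scripts/acceptance.py` uses 200–300
  replicates per cell (a few minutes on one CPU). One adaptive
  replicate (two fits) takes ~0.3 s at the small cells; a fixed-design
  fit at the largest cell (200 clusters, 10 000 participants) ~3 s.

## What the generator does and does not emulate

It emulates: whole-cluster enrolment, between-cluster heterogeneity at
a specified latent ICC, scenario-defined effect sizes, balanced
round-robin recruitment, and post-interim reallocation. It does **not**
emulate: unequal cluster sizes, covariates or confounder imbalance,
time or learning effects, participant-level non-exchangeability within
clusters, multiple interims, or outcome misclassification. Passing
tests therefore certify the engine's operating characteristics under
an idealised trial, not the behaviour of any real trial with these
features.

## Known limitations

- The tight `half-N(0, 0.2)` hyperprior under-covers at high ICC (see
  calibration above); both prior scales are exposed for sensitivity
  analyses.
- One interim only; dropping is limited to one arm per interim.
- The trajectory sampler uses slice (not multinomial) selection across
  the NUTS tree; both target the same posterior, with slightly
  different per-iteration efficiency.
- Decision frequencies condition on the interim fit producing draws;
  interim fit failures abort the replicate and are tallied as errors
  rather than decisions.
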