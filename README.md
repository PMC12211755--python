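# adaptcrt

Simulation engine for evaluating **Bayesian adaptive, multi-arm,
cluster-randomised controlled trials (cRCTs) with few clusters** — the
setting typical of implementation-science trials that try to pick the
best of several implementation strategies when whole schools, clinics
or wards are randomised and only a handful of clusters per arm is
feasible.

The package answers design questions by Monte Carlo: for a four-arm
cRCT with a binary outcome, it simulates trials under configurable
effect-size scenarios, intra-class correlations (ICC), cluster sizes
and cluster counts; analyses each trial with a hierarchical Bayesian
logistic model; applies interim **arm-dropping** and
**stopping-for-futility** rules; and estimates power, type-1 error,
interim-decision frequencies and MCMC convergence rates for the
adaptive and the fixed (non-adaptive) versions of each design.

## The model

Outcomes are generated from a logistic random-intercept model for
participant *i* in cluster *m* of arm *j* (arm 1 is control):

```
Y_imj ~ Bernoulli(p_mj)
logit(p_mj) = beta_0 + X_mj beta_j + alpha_m,   alpha_m ~ N(0, sigma_a)
sigma_a = sqrt( ICC * (pi^2/3) / (1 - ICC) )
```

Each simulated trial is analysed with the hierarchical Bayesian model

```
Y ~ Bernoulli( inv_logit( theta_1 + W alpha + X_2 theta_2 + X_3 theta_3 + X_4 theta_4 ) )
theta_1..theta_4 ~ N(0, 2)
alpha_m ~ N(0, sigma_a),  sigma_a ~ half-N(0, 0.2)
```

sampled by a No-U-Turn sampler (4 chains, 750 warmup + 750 draws each,
target acceptance 0.99, non-centered cluster effects) implemented in
numba inside the package. The quantity that drives every decision is
the posterior probability that arm *j* is best,
`P(theta_j = max{theta_1..theta_4} | data)`, estimated as the fraction
of posterior draws in which arm *j* has the largest arm-level effect.

Interim rules (once half the planned clusters per arm are in): stop the
whole trial for futility if every treatment arm has P(best) < 0.3;
otherwise drop the single worst treatment arm if its P(best) < 0.05
(ties broken by the lower effect estimate; the control is never
dropped) and reallocate its unspent clusters to the remaining arms. A
completed trial is a success if the truly best arm ends with
P(best) ≥ 0.95; in the null scenario any arm reaching 0.95 is an
(incorrect) success, which defines the type-1 error.

## Worked example

`examples/run_one_adaptive_trial.py` simulates one adaptive trial
(scenario 2 — a less clear optimal arm with event probabilities
0.1/0.3/0.4/0.5 — ICC 0.1, 25 participants per cluster, 5 clusters per
arm) and prints:

```
interim decision : continue_all
interim P(best)  : [0.    0.26  0.147 0.593]
clusters per arm : (5, 5, 5, 5)
final P(best)    : [0.    0.078 0.112 0.809]
trial success    : False
```

At the interim (3 clusters per arm) no treatment arm was weak enough to
drop and the arms were not jointly futile, so the trial completed all
20 clusters. Arm 4 — the truly best arm — finished with posterior
probability 0.809 of being best, short of the 0.95 success cut-point,
so this replicate is counted as a non-success when estimating power.

Other examples: `examples/fit_posterior_model.py` (posterior recovery
of the generating log-odds ratios plus R-hat/ESS diagnostics) and
`examples/small_design_study.py` (a miniature design study through
`run_study`/`report`).

## Command line

```bash
adaptcrt simulate --scenario 1 --icc 0.05 --n 25 --k 5 --reps 100 \
    --seed 7 --out results/
adaptcrt report --in results/ --figures
```

`simulate` runs replicates over a (restrictable) factorial design grid
with per-replicate seed substreams, checkpointing raw per-trial rows to
CSV shards so interrupted runs resume; `report` aggregates them into
power / type-1 / decision / convergence tables with Monte Carlo
standard errors. A YAML/JSON config file (`--config`) can set the grid,
the rule thresholds and the sampler settings; flags override it.

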