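"""Fit the hierarchical Bayesian model to one simulated dataset.

Simulates a fixed four-arm trial (scenario 1: event probabilities
0.1/0.2/0.4/0.6), fits the random-intercept logistic model by NUTS, and
compares posterior means of the treatment contrasts (log-odds ratios vs
control) with the values that generated the data.
"""

import numpy as np

from adaptcrt import (
    SamplerSettings, TrialConfig, TrialScenario,
    fit_model, prob_best, simulate_clusters,
)
from adaptcrt.dgm import scenario_to_log_odds

config = TrialConfig(
    scenario=TrialScenario.from_id(1), icc=0.05,
    n_per_cluster=50, k_per_arm=10, adaptive=False,
)
beta0, beta = scenario_to_log_odds(config.scenario)

rng = np.random.default_rng(7)
data = simulate_clusters(config, {arm: 10 for arm in (1, 2, 3, 4)}, rng)
fit = fit_model(data, SamplerSettings(), np.random.default_rng(8))

print("generating contrasts :", np.round(beta, 3))
print("posterior means      :", np.round(fit.contrast_means(), 3))
print("posterior SDs        :", np.round(fit.contrast_draws.std(axis=0), 3))
print("P(best) per arm      :", np.round(prob_best(fit).p_best, 3))
print("convergence flagged  :", fit.diagnostics.flagged,
      "| worst diagnostics:", fit.diagnostics.worst())

# With 10 clusters x 50 participants per arm the contrasts are recovered
# to within a posterior SD or two, arm 4 holds nearly all of the
# probability of being best, and R-hat/ESS are comfortably clean.
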