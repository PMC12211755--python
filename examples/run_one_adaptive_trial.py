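"""Simulate and analyse a single adaptive four-arm cluster trial.

Builds one design cell (scenario 2, ICC 0.1, 25 participants per
cluster, 5 clusters per arm), runs the trial through its interim
analysis, and prints the interim decision and the final posterior
probabilities of each arm being best.
"""

import numpy as np

from adaptcrt import TrialConfig, TrialScenario, run_trial

config = TrialConfig(
    scenario=TrialScenario.from_id(2),   # less clear optimal arm
    icc=0.1,
    n_per_cluster=25,
    k_per_arm=5,
    adaptive=True,
)

result = run_trial(config, np.random.SeedSequence(2024))

print(f"interim decision : {result.decision.kind}"
      + (f" (arm {result.decision.dropped_arm})"
         if result.decision.dropped_arm else ""))
print("interim P(best)  :",
      np.round(result.decision.p_best_at_interim.p_best, 3))
print("clusters per arm :", result.clusters_recruited_per_arm)
if result.final_p_best is not None:
    print("final P(best)    :", np.round(result.final_p_best.p_best, 3))
print(f"trial success    : {result.success}")

# The interim fires at 3 of 5 clusters per arm.  A dropped arm keeps its
# interim clusters in the final analysis but recruits no more; its
# unspent budget is split over the remaining arms.  The trial is a
# success if arm 4 (the truly best arm) ends with P(best) >= 0.95.
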