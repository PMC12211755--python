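"""Data-generating mechanism: logistic random-intercept cluster trials.

Outcomes are binary.  For participant *i* in cluster *m* assigned to arm
*j*::

    Y_imj ~ Bernoulli(p_mj)
    logit(p_mj) = beta0 + beta_j * [arm j] + alpha_m
    alpha_m ~ Normal(0, sigma_a)

with the latent-scale cluster SD derived from the intra-class
correlation via ``sigma_a = sqrt(ICC * (pi^2/3) / (1 - ICC))`` (the
residual variance of a logistic latent variable is pi^2/3).

Scenario event probabilities are interpreted on the conditional
(cluster-specific, alpha = 0) scale: ``beta0 = logit(p_control)``
exactly.  At ICC > 0 the marginal event proportion is therefore biased
upward for p < 0.5; this is a property of simulating population-level
targets through a subject-specific model, shared equally by all arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import TrialConfig, TrialScenario

__all__ = [
    "icc_to_sd",
    "scenario_to_log_odds",
    "ClusterDataset",
    "simulate_clusters",
    "extend_dataset",
]

_COLUMNS = ["participant", "cluster", "arm", "outcome"]


def icc_to_sd(icc: float) -> float:
    """Latent-scale cluster SD implied by an intra-class correlation.

    Solves ICC = sigma_a^2 / (sigma_a^2 + pi^2/3) for sigma_a.
    """
    if not (0.0 <= icc < 1.0):
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    return math.sqrt(icc * (math.pi ** 2 / 3.0) / (1.0 - icc))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def scenario_to_log_odds(scenario: TrialScenario) -> tuple[float, np.ndarray]:
    """Map scenario event probabilities to (intercept, treatment contrasts).

    Returns ``beta0 = logit(p_control)`` and the three log-odds ratios
    ``beta_j = logit(p_{j+1}) - logit(p_control)`` for arms 2-4.
    """
    probs = scenario.arm_probabilities
    beta0 = _logit(probs[0])
    beta = np.array([_logit(p) - beta0 for p in probs[1:]])
    return beta0, beta


@dataclass
class ClusterDataset:
    """Long-format simulated trial data.

    ``data`` holds one row per participant with columns
    (participant, cluster, arm, outcome); ``recruitment_order`` lists
    cluster indices in the order the clusters were enrolled (enrolment is
    an entire cluster at a time).
    """

    data: pd.DataFrame
    recruitment_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        out = self.data["outcome"].to_numpy()
        if out.size and not np.isin(out, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.data["cluster"].to_numpy())

    @property
    def n_clusters(self) -> int:
        return self.cluster_ids.size

    def clusters_per_arm(self) -> dict[int, int]:
        """Number of distinct clusters recruited to each arm (1-4)."""
        per = (self.data.drop_duplicates("cluster").groupby("arm")["cluster"]
               .count().to_dict())
        return {arm: int(per.get(arm, 0)) for arm in (1, 2, 3, 4)}

    def cluster_summary(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-cluster sufficient statistics for the binomial likelihood.

        Returns (cluster_ids, successes, sizes, arm) with clusters in
        ascending index order; within a cluster every participant shares
        one linear predictor, so the per-cluster success count is
        sufficient.
        """
        g = self.data.groupby("cluster")
        ids = np.array(sorted(g.groups))
        agg = g.agg(successes=("outcome", "sum"), size=("outcome", "count"),
                    arm=("arm", "first")).loc[ids]
        return (ids, agg["successes"].to_numpy(dtype=np.float64),
                agg["size"].to_numpy(dtype=np.float64),
                agg["arm"].to_numpy(dtype=np.int64))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClusterDataset":
        df = pd.read_csv(path)
        order = list(df.drop_duplicates("cluster")["cluster"])
        return cls(df[_COLUMNS].copy(), order)


def _round_robin(allocation: Mapping[int, int]) -> list[int]:
    """Interleave arm labels so recruitment stays balanced at any cut."""
    counts = {int(a): int(c) for a, c in allocation.items()}
    order: list[int] = []
    while any(c > 0 for c in counts.values()):
        for arm in sorted(counts):
            if counts[arm] > 0:
                order.append(arm)
                counts[arm] -= 1
    return order


def _simulate_block(
    config: TrialConfig,
    allocation: Mapping[int, int],
    rng: np.random.Generator,
    first_cluster: int,
) -> pd.DataFrame:
    for arm, cnt in allocation.items():
        if int(arm) not in (1, 2, 3, 4):
            raise ValueError(f"unknown arm index {arm}")
        if int(cnt) < 0:
            raise ValueError(f"negative cluster count {cnt} for arm {arm}")
    beta0, beta = scenario_to_log_odds(config.scenario)
    sigma_a = icc_to_sd(config.icc)
    n = config.n_per_cluster
    rows = []
    cluster = first_cluster
    for arm in _round_robin(allocation):
        alpha = rng.normal(0.0, sigma_a) if sigma_a > 0 else 0.0
        eta = beta0 + (beta[arm - 2] if arm > 1 else 0.0) + alpha
        p = 1.0 / (1.0 + math.exp(-eta))
        y = (rng.random(n) < p).astype(np.int64)
        rows.append(pd.DataFrame({
            "participant": np.arange(1, n + 1),
            "cluster": cluster,
            "arm": arm,
            "outcome": y,
        }))
        cluster += 1
    if not rows:
        raise ValueError("allocation assigns no clusters")
    return pd.concat(rows, ignore_index=True)


def simulate_clusters(
    config: TrialConfig,
    allocation: Mapping[int, int],
    rng: np.random.Generator,
) -> ClusterDataset:
    """Simulate a fresh trial dataset with the given arm -> cluster counts.

    Clusters are enrolled one at a time, round-robin across arms, each
    with its own random intercept and ``n_per_cluster`` Bernoulli
    outcomes.  Identical (config, allocation, generator state) yields an
    identical dataset.
    """
    if not allocation or all(int(c) == 0 for c in allocation.values()):
        raise ValueError("allocation must assign at least one cluster")
    df = _simulate_block(config, allocation, rng, first_cluster=1)
    order = list(df.drop_duplicates("cluster")["cluster"])
    return ClusterDataset(df, order)


def extend_dataset(
    existing: ClusterDataset,
    config: TrialConfig,
    allocation: Mapping[int, int],
    rng: np.random.Generator,
) -> ClusterDataset:
    """Recruit additional clusters after an interim decision.

    New clusters get fresh random intercepts and globally unique indices;
    existing rows are unchanged.  An all-zero allocation returns an
    equivalent dataset.
    """
    for arm, cnt in allocation.items():
        if int(cnt) < 0:
            raise ValueError(f"negative cluster count {cnt} for arm {arm}")
    if all(int(c) == 0 for c in allocation.values()):
        return ClusterDataset(existing.data.copy(),
                              list(existing.recruitment_order))
    first = int(existing.cluster_ids.max()) + 1 if existing.n_rows else 1
    new = _simulate_block(config, allocation, rng, first_cluster=first)
    df = pd.concat([existing.data, new], ignore_index=True)
    order = list(existing.recruitment_order) + \
        list(new.drop_duplicates("cluster")["cluster"])
    return ClusterDataset(df, order)
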