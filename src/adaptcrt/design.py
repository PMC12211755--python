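"""Trial scenarios, design-grid construction, and configuration validation.

The design space is a fully factorial grid over effect-size scenario,
intra-class correlation (ICC), participants per cluster (n), clusters per
arm (k), and whether the adaptive rules (arm dropping + stopping for
futility) are switched on.  Every simulated trial is a four-arm
cluster-randomised trial with a binary outcome; arm 1 is the control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "SCENARIO_PROBABILITIES",
    "TrialScenario",
    "AdaptiveRuleConfig",
    "SamplerSettings",
    "TrialConfig",
    "build_grid",
]

#: Event probabilities (control, arm 2, arm 3, arm 4) for the three
#: effect-size scenarios: 1 = clearer optimal arm, 2 = less clear optimal
#: arm, 3 = null (no effect, used for type-1 error).
SCENARIO_PROBABILITIES: dict[int, tuple[float, float, float, float]] = {
    1: (0.1, 0.2, 0.4, 0.6),
    2: (0.1, 0.3, 0.4, 0.5),
    3: (0.1, 0.1, 0.1, 0.1),
}


class DesignValidationError(ValueError):
    """A trial configuration field is outside its valid range."""


@dataclass(frozen=True)
class TrialScenario:
    """One effect-size scenario: four per-arm event probabilities.

    Arm 4 is the optimal arm in the non-null scenarios; in the null
    scenario all arms share the control probability.
    """

    scenario_id: int
    arm_probabilities: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.arm_probabilities) != 4:
            raise DesignValidationError(
                "arm_probabilities: exactly 4 probabilities required, got "
                f"{len(self.arm_probabilities)}"
            )
        for p in self.arm_probabilities:
            if not (0.0 < p < 1.0):
                raise DesignValidationError(
                    f"arm_probabilities: {p} is not strictly inside (0, 1)"
                )
        if not self.is_null:
            best = self.arm_probabilities[3]
            if any(best <= p for p in self.arm_probabilities[:3]):
                raise DesignValidationError(
                    "arm 4 must have the strictly largest event probability "
                    "in a non-null scenario"
                )

    @property
    def is_null(self) -> bool:
        probs = self.arm_probabilities
        return all(p == probs[0] for p in probs)

    @classmethod
    def from_id(cls, scenario_id: int) -> "TrialScenario":
        try:
            probs = SCENARIO_PROBABILITIES[int(scenario_id)]
        except KeyError:
            raise DesignValidationError(
                f"scenario_id: unknown scenario {scenario_id!r}; expected 1, 2 or 3"
            ) from None
        return cls(int(scenario_id), probs)


@dataclass(frozen=True)
class AdaptiveRuleConfig:
    """Thresholds for the interim decision rules.

    drop_threshold
        An arm is a candidate for dropping when its posterior probability
        of being the best arm falls below this value.
    futility_threshold
        The trial stops for futility when *every* treatment arm's
        posterior probability of being best is below this value.
    success_threshold
        At the final analysis the trial is a success when the optimal
        arm's posterior probability of being best reaches this value.
    interim_fraction
        The interim analysis happens once this fraction of the planned
        clusters per arm has been recruited (rounded up).
    """

    drop_threshold: float = 0.05
    futility_threshold: float = 0.3
    success_threshold: float = 0.95
    interim_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("drop_threshold", "futility_threshold",
                     "success_threshold", "interim_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DesignValidationError(
                    f"{name}: {v} is not strictly inside (0, 1)"
                )
        if not self.drop_threshold < self.futility_threshold:
            raise DesignValidationError(
                "drop_threshold must be smaller than futility_threshold "
                f"({self.drop_threshold} >= {self.futility_threshold})"
            )


@dataclass(frozen=True)
class SamplerSettings:
    """No-U-Turn sampler configuration for the hierarchical model.

    The defaults match common practice for weak clustered data: 4 chains
    of 750 warmup + 750 retained draws, a high target acceptance
    probability (0.99 rather than the usual 0.8) so the sampler takes
    small, robust steps, and a non-centered parameterisation of the
    cluster random effects.
    """

    chains: int = 4
    warmup_per_chain: int = 750
    draws_per_chain: int = 750
    target_acceptance: float = 0.99
    non_centered: bool = True
    max_treedepth: int = 10
    theta_prior_scale: float = 2.0
    sigma_prior_scale: float = 0.2
    divergence_cap_fraction: float = 0.25

    def __post_init__(self) -> None:
        for name in ("chains", "warmup_per_chain", "draws_per_chain",
                     "max_treedepth"):
            if int(getattr(self, name)) < 1:
                raise DesignValidationError(f"{name} must be a positive integer")
        if not (0.0 < self.target_acceptance < 1.0):
            raise DesignValidationError(
                f"target_acceptance: {self.target_acceptance} not in (0, 1)"
            )
        for name in ("theta_prior_scale", "sigma_prior_scale"):
            if getattr(self, name) <= 0:
                raise DesignValidationError(f"{name} must be positive")

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain


@dataclass(frozen=True)
class TrialConfig:
    """One cell of the design space.

    ``seed`` is the cell's substream index under the study master seed;
    replicate streams are spawned as (master_seed, seed, replicate).
    """

    scenario: TrialScenario
    icc: float
    n_per_cluster: int
    k_per_arm: int
    adaptive: bool
    rules: AdaptiveRuleConfig = field(default_factory=AdaptiveRuleConfig)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.icc < 1.0):
            raise DesignValidationError(
                f"icc: {self.icc} must lie in [0, 1); an ICC of 1 implies an "
                "infinite latent cluster SD"
            )
        if int(self.n_per_cluster) < 1:
            raise DesignValidationError(
                f"n_per_cluster: {self.n_per_cluster} must be >= 1"
            )
        min_k = 2 if self.adaptive else 1
        if int(self.k_per_arm) < min_k:
            raise DesignValidationError(
                f"k_per_arm: {self.k_per_arm} must be >= {min_k}"
                + (" for an adaptive design (an interim at fewer than 2 "
                   "clusters per arm is disallowed)" if self.adaptive else "")
            )
        if int(self.seed) < 0:
            raise DesignValidationError(f"seed: {self.seed} must be non-negative")
        if self.adaptive:
            # fail early rather than inside the trial loop
            from .adaptive import interim_cluster_count

            interim_cluster_count(self.k_per_arm, self.rules.interim_fraction)

    @property
    def total_clusters(self) -> int:
        return 4 * self.k_per_arm

    @property
    def cell_key(self) -> tuple:
        return (self.scenario.scenario_id, self.icc, self.n_per_cluster,
                self.k_per_arm, self.adaptive)

    def cell_label(self) -> str:
        kind = "adaptive" if self.adaptive else "fixed"
        return (f"s{self.scenario.scenario_id}_icc{self.icc:g}_"
                f"n{self.n_per_cluster}_k{self.k_per_arm}_{kind}")


def build_grid(
    scenarios: Sequence[TrialScenario | int],
    iccs: Sequence[float],
    ns: Sequence[int],
    ks: Sequence[int],
    adaptive_flags: Sequence[bool],
    rules: AdaptiveRuleConfig | None = None,
    sampler: SamplerSettings | None = None,
) -> list[TrialConfig]:
    """Cartesian product of design factors, as validated configurations.

    Each configuration receives a distinct deterministic seed-substream
    index (its position in the product ordering), so any cell of any
    study is reproducible in isolation.
    """
    for name, lst in (("scenarios", scenarios), ("iccs", iccs), ("ns", ns),
                      ("ks", ks), ("adaptive_flags", adaptive_flags)):
        if len(lst) == 0:
            raise DesignValidationError(f"{name}: empty factor list")
    rules = rules if rules is not None else AdaptiveRuleConfig()
    sampler = sampler if sampler is not None else SamplerSettings()
    scen_objs = [s if isinstance(s, TrialScenario) else TrialScenario.from_id(s)
                 for s in scenarios]
    grid = []
    for idx, (sc, icc, n, k, ad) in enumerate(
            itertools.product(scen_objs, iccs, ns, ks, adaptive_flags)):
        grid.append(TrialConfig(
            scenario=sc, icc=float(icc), n_per_cluster=int(n),
            k_per_arm=int(k), adaptive=bool(ad), rules=rules,
            sampler=sampler, seed=idx,
        ))
    return grid
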