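"""Single-trial execution: fixed designs and the adaptive interim rules.

An adaptive trial runs one interim analysis once a configurable fraction
(default half, rounded up) of the planned clusters per arm is recruited.
At the interim the posterior probability of each arm being best is
computed and the rules are applied in order of precedence:

1. *Stop for futility* if every treatment arm's probability of being
   best is below the futility threshold (the whole trial ends, no
   success possible).
2. Otherwise *drop at most one arm*: among treatment arms whose
   probability of being best is below the drop threshold, the one with
   the lowest probability (ties broken by the lowest posterior-mean
   effect estimate) stops recruiting.  The control arm is never dropped.
3. Otherwise continue with all arms.

The cluster budget not yet recruited is then split as evenly as possible
over the remaining arms (randomised remainder), the trial completes, and
the final model is fitted on all accumulated data -- including the
interim clusters of a dropped arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .design import AdaptiveRuleConfig, TrialConfig
from .dgm import ClusterDataset, extend_dataset, simulate_clusters
from .model import (
    BestArmProbabilities,
    ConvergenceDiagnostics,
    FitError,
    PosteriorFit,
    fit_model,
    prob_best,
)

__all__ = [
    "InterimDecision",
    "TrialResult",
    "interim_cluster_count",
    "futility_decision",
    "arm_drop_decision",
    "reallocate_clusters",
    "run_trial",
]

CONTINUE_ALL = "continue_all"
DROP_ARM = "drop_arm"
STOP_FUTILITY = "stop_futility"


@dataclass(frozen=True)
class InterimDecision:
    kind: str
    dropped_arm: int | None
    p_best_at_interim: BestArmProbabilities
    interim_diagnostics: ConvergenceDiagnostics | None

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUE_ALL, DROP_ARM, STOP_FUTILITY):
            raise ValueError(f"unknown decision kind {self.kind!r}")
        if (self.dropped_arm is not None) != (self.kind == DROP_ARM):
            raise ValueError("dropped_arm must be present iff kind == drop_arm")
        if self.dropped_arm is not None and self.dropped_arm not in (2, 3, 4):
            raise ValueError("the control arm can never be dropped")


@dataclass
class TrialResult:
    """Outcome of one simulated trial replicate."""

    config: TrialConfig
    decision: InterimDecision | None
    final_p_best: BestArmProbabilities | None
    success: bool
    clusters_recruited_per_arm: tuple[int, int, int, int]
    final_diagnostics: ConvergenceDiagnostics | None
    final_fit: PosteriorFit | None = None
    error: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.clusters_recruited_per_arm)
        if total > self.config.total_clusters:
            raise ValueError("recruited more clusters than planned")
        if self.decision is not None and self.decision.kind == STOP_FUTILITY:
            if self.success:
                raise ValueError("a futility-stopped trial cannot succeed")
        elif self.error is None and total != self.config.total_clusters:
            raise ValueError("a completed trial must use the full budget")

    @property
    def any_flagged(self) -> bool:
        flags = []
        if self.decision is not None and self.decision.interim_diagnostics:
            flags.append(self.decision.interim_diagnostics.flagged)
        if self.final_diagnostics is not None:
            flags.append(self.final_diagnostics.flagged)
        return any(flags)


def interim_cluster_count(k_per_arm: int, interim_fraction: float) -> int:
    """Per-arm cluster count at which the interim analysis runs.

    The interim happens once at least ``interim_fraction`` of the
    planned ``k_per_arm`` clusters is recruited in every arm, i.e. at
    ``ceil(k_per_arm * interim_fraction)`` clusters per arm (3 of 5,
    5 of 10 at the default half).
    """
    if k_per_arm < 2:
        raise ValueError("adaptive designs need k_per_arm >= 2")
    count = math.ceil(k_per_arm * interim_fraction)
    if count >= k_per_arm:
        raise ValueError(
            f"interim at {count} of {k_per_arm} clusters per arm would not "
            "precede trial completion")
    return count


def futility_decision(p_best: BestArmProbabilities,
                      rules: AdaptiveRuleConfig) -> bool:
    """True when every treatment arm is below the futility threshold.

    The control arm's probability of being best is not consulted.
    """
    return all(p_best[j] < rules.futility_threshold for j in (2, 3, 4))


def arm_drop_decision(
    p_best: BestArmProbabilities,
    contrast_posterior_means: Iterable[float],
    rules: AdaptiveRuleConfig,
) -> int | None:
    """Arm (2-4) to drop, or None if no arm qualifies.

    Candidates are treatment arms whose probability of being best is
    below the drop threshold; the one with the lowest probability is
    dropped, with ties broken by the lowest posterior-mean effect
    estimate.  At most one arm is dropped per interim.
    """
    means = list(contrast_posterior_means)
    if len(means) != 3:
        raise ValueError("need 3 contrast posterior means (arms 2-4)")
    candidates = [j for j in (2, 3, 4) if p_best[j] < rules.drop_threshold]
    if not candidates:
        return None
    return min(candidates, key=lambda j: (p_best[j], means[j - 2]))


def reallocate_clusters(
    k_per_arm: int,
    interim_count: int,
    remaining_arms: Iterable[int],
    rng: np.random.Generator,
) -> dict[int, int]:
    """Split the unrecruited cluster budget over the remaining arms.

    The budget ``4*k_per_arm - 4*interim_count`` is divided as evenly as
    possible; any remainder goes to arms chosen uniformly at random
    without replacement.
    """
    arms = sorted(set(int(a) for a in remaining_arms))
    if not arms:
        raise ValueError("remaining_arms must be non-empty")
    if 1 not in arms:
        raise ValueError("the control arm must always remain")
    budget = 4 * k_per_arm - 4 * interim_count
    if budget < 0:
        raise ValueError("negative remaining cluster budget")
    base, rem = divmod(budget, len(arms))
    alloc = {a: base for a in arms}
    if rem:
        for a in rng.choice(arms, size=rem, replace=False):
            alloc[int(a)] += 1
    return alloc


def _safe_fit(data, config, rng):
    return fit_model(data, config.sampler, rng)


def run_trial(config: TrialConfig, rng_state) -> TrialResult:
    """Simulate and analyse one trial replicate.

    ``rng_state`` is a :class:`numpy.random.SeedSequence` (or an int
    seed); data generation and model fitting consume independent child
    streams so the simulated data are invariant to sampler settings.
    Fit failures are recorded on the result rather than raised, so
    replicate batches keep running.
    """
    ss = (rng_state if isinstance(rng_state, np.random.SeedSequence)
          else np.random.SeedSequence(rng_state))
    data_ss, fit_ss = ss.spawn(2)
    data_rng = np.random.default_rng(data_ss)
    fit_rng = np.random.default_rng(fit_ss)
    k = config.k_per_arm

    if not config.adaptive:
        data = simulate_clusters(config, {a: k for a in (1, 2, 3, 4)}, data_rng)
        counts = tuple(data.clusters_per_arm()[a] for a in (1, 2, 3, 4))
        try:
            fit = _safe_fit(data, config, fit_rng)
        except FitError as exc:
            return TrialResult(config, None, None, False, counts,
                               exc.diagnostics, error=str(exc))
        pb = prob_best(fit)
        return TrialResult(config, None, pb,
                           _success(pb, config), counts, fit.diagnostics,
                           final_fit=fit)

    ic = interim_cluster_count(k, config.rules.interim_fraction)
    data = simulate_clusters(config, {a: ic for a in (1, 2, 3, 4)}, data_rng)
    counts_interim = tuple(data.clusters_per_arm()[a] for a in (1, 2, 3, 4))
    try:
        interim_fit = _safe_fit(data, config, fit_rng)
    except FitError as exc:
        return TrialResult(config, None, None, False, counts_interim,
                           None, error=f"interim: {exc}")

    pb_interim = prob_best(interim_fit)
    # futility takes precedence: if both rules fire the trial stops early
    if futility_decision(pb_interim, config.rules):
        decision = InterimDecision(STOP_FUTILITY, None, pb_interim,
                                   interim_fit.diagnostics)
        return TrialResult(config, decision, None, False, counts_interim, None)

    dropped = arm_drop_decision(pb_interim, interim_fit.contrast_means(),
                                config.rules)
    if dropped is not None:
        decision = InterimDecision(DROP_ARM, dropped, pb_interim,
                                   interim_fit.diagnostics)
    else:
        decision = InterimDecision(CONTINUE_ALL, None, pb_interim,
                                   interim_fit.diagnostics)
    remaining = [a for a in (1, 2, 3, 4) if a != dropped]
    alloc = reallocate_clusters(k, ic, remaining, data_rng)
    data = extend_dataset(data, config, alloc, data_rng)
    counts = tuple(data.clusters_per_arm()[a] for a in (1, 2, 3, 4))

    try:
        final_fit = _safe_fit(data, config, fit_rng)
    except FitError as exc:
        return TrialResult(config, decision, None, False, counts,
                           exc.diagnostics, error=f"final: {exc}")
    pb_final = prob_best(final_fit)
    return TrialResult(config, decision, pb_final,
                       _success(pb_final, config), counts,
                       final_fit.diagnostics, final_fit=final_fit)


def _success(pb: BestArmProbabilities, config: TrialConfig) -> bool:
    from .performance import trial_success

    return trial_success(pb, config.scenario, config.rules)
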