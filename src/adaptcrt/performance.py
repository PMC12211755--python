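"""Operating characteristics: power, type-1 error, decision frequencies.

A completed trial is a *success* when the optimal arm's posterior
probability of being the best arm reaches the success threshold
(default 0.95).  Power is the proportion of successes in a non-null
scenario; type-1 error is the proportion of (incorrect) successes in
the null scenario, where a success is *any* treatment arm reaching the
threshold.  Monte Carlo standard errors use the binomial formula
``sqrt(p(1-p)/n_reps)``, and the repetition planner inverts it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .adaptive import CONTINUE_ALL, DROP_ARM, STOP_FUTILITY, TrialResult
from .design import AdaptiveRuleConfig, TrialScenario

__all__ = [
    "OperatingCharacteristics",
    "trial_success",
    "aggregate",
    "required_repetitions",
    "tabulate_decisions",
]

logger = logging.getLogger(__name__)


def trial_success(
    p_best,
    scenario: TrialScenario,
    rules: AdaptiveRuleConfig,
) -> bool:
    """Was the trial (correctly or incorrectly) declared a success?

    Non-null scenarios: the optimal arm (arm 4) must reach the success
    threshold.  Null scenario: any treatment arm reaching the threshold
    is an incorrect success (a type-1 event); no multiplicity correction
    is applied -- the disjunction itself is the type-1 definition.
    """
    if scenario.is_null:
        return any(p_best[j] >= rules.success_threshold for j in (2, 3, 4))
    return p_best[4] >= rules.success_threshold


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte Carlo summary for one design cell."""

    cell_key: tuple
    n_reps: int
    success_proportion: float
    mcse: float
    futility_stop_proportion: float
    drop_proportion_per_arm: tuple[float, float, float]
    continue_all_proportion: float
    convergence_flag_proportion: float
    fit_failure_proportion: float

    def as_row(self) -> dict:
        scenario, icc, n, k, adaptive = self.cell_key
        row = {
            "scenario": scenario, "icc": icc, "n_per_cluster": n,
            "k_per_arm": k, "adaptive": adaptive, "n_reps": self.n_reps,
            "success_proportion": self.success_proportion, "mcse": self.mcse,
            "futility_stop_proportion": self.futility_stop_proportion,
            "continue_all_proportion": self.continue_all_proportion,
            "convergence_flag_proportion": self.convergence_flag_proportion,
            "fit_failure_proportion": self.fit_failure_proportion,
        }
        for arm, p in zip((2, 3, 4), self.drop_proportion_per_arm):
            row[f"drop_arm{arm}_proportion"] = p
        return row


def required_repetitions(power_guess: float, target_mcse: float) -> int:
    """Simulation count needed for a target Monte Carlo SE of a proportion.

    ``ceil(p(1-p)/mcse^2)``; at the worst case p = 0.5 and a 1% target
    this gives 2500 repetitions.
    """
    if not (0.0 < power_guess < 1.0):
        raise ValueError(f"power_guess must lie in (0, 1), got {power_guess}")
    if not target_mcse > 0.0:
        raise ValueError("target_mcse must be positive")
    return math.ceil(power_guess * (1.0 - power_guess) / target_mcse ** 2)


def aggregate(results: Sequence[TrialResult]) -> OperatingCharacteristics:
    """Reduce replicates from one design cell to operating characteristics.

    Replicates with failed fits count as non-successes in the
    denominator and are reported as a separate failure proportion.
    Order of the input list is irrelevant.
    """
    if not results:
        raise ValueError("no results to aggregate")
    keys = {r.config.cell_key for r in results}
    if len(keys) > 1:
        raise ValueError(f"results mix design cells: {sorted(keys)}")
    n = len(results)
    succ = sum(r.success for r in results) / n
    futility = sum(
        1 for r in results
        if r.decision is not None and r.decision.kind == STOP_FUTILITY) / n
    drops = tuple(
        sum(1 for r in results
            if r.decision is not None and r.decision.kind == DROP_ARM
            and r.decision.dropped_arm == arm) / n
        for arm in (2, 3, 4))
    cont = sum(
        1 for r in results
        if r.decision is not None and r.decision.kind == CONTINUE_ALL) / n
    flagged = sum(r.any_flagged for r in results) / n
    failed = sum(r.error is not None for r in results) / n
    return OperatingCharacteristics(
        cell_key=next(iter(keys)),
        n_reps=n,
        success_proportion=succ,
        mcse=math.sqrt(succ * (1.0 - succ) / n),
        futility_stop_proportion=futility,
        drop_proportion_per_arm=drops,
        continue_all_proportion=cont,
        convergence_flag_proportion=flagged,
        fit_failure_proportion=failed,
    )


def tabulate_decisions(results: Iterable[TrialResult]) -> pd.DataFrame:
    """Interim decision frequencies per design cell (adaptive trials).

    Returns one row per cell with the proportions of continue-all,
    drop-arm-2/3/4, and stop-for-futility decisions; rows partition the
    replicates, so the five proportions sum to 1.  Replicates whose
    interim fit failed (no decision) are excluded from the denominator
    with a logged warning.
    """
    by_cell: dict[tuple, list[TrialResult]] = {}
    n_skipped = 0
    for r in results:
        if not r.config.adaptive:
            raise ValueError("tabulate_decisions expects adaptive results only")
        if r.decision is None:
            n_skipped += 1
            continue
        by_cell.setdefault(r.config.cell_key, []).append(r)
    if n_skipped:
        logger.warning("%d replicates had no interim decision (fit failures)",
                       n_skipped)
    rows = []
    for key in sorted(by_cell):
        cell = by_cell[key]
        n = len(cell)
        scenario, icc, npc, k, _ = key
        row = {
            "scenario": scenario, "icc": icc, "n_per_cluster": npc,
            "k_per_arm": k, "n_decisions": n,
            "continue_all": sum(r.decision.kind == CONTINUE_ALL
                                for r in cell) / n,
            "stop_futility": sum(r.decision.kind == STOP_FUTILITY
                                 for r in cell) / n,
        }
        for arm in (2, 3, 4):
            row[f"drop_arm{arm}"] = sum(
                r.decision.kind == DROP_ARM and r.decision.dropped_arm == arm
                for r in cell) / n
        rows.append(row)
    if not rows:
        logger.warning("no adaptive decisions to tabulate")
    return pd.DataFrame(rows)
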