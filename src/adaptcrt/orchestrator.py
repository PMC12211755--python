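"""Study orchestration: replicate batches over the design grid.

``run_study`` executes the requested number of trial replicates for
every cell of a design grid, with a counter-based seed scheme -- the
stream for replicate *r* of cell *c* is
``SeedSequence(master_seed, spawn_key=(c, r))`` -- so any replicate is
reproducible in isolation and results are identical for any worker
count or scheduling order.  Raw per-trial rows are checkpointed to
per-cell CSV shards (a replicate is the expensive unit, as each one
involves one or two MCMC fits), and interrupted runs resume where they
stopped.  ``report`` turns a results directory into aggregate
side-by-side tables for the adaptive and fixed designs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptive import TrialResult, run_trial
from .design import (
    AdaptiveRuleConfig,
    SamplerSettings,
    TrialConfig,
    build_grid,
)

__all__ = ["RunManifest", "load_study_config", "study_grid", "run_study",
           "report", "replicate_seed"]

logger = logging.getLogger(__name__)

_DEFAULT_GRID = {
    "scenarios": [1, 2, 3],
    "iccs": [0.05, 0.1, 0.2],
    "ns": [5, 25, 50],
    "ks": [5, 10],
    "adaptive": [True, False],
}


@dataclass
class RunManifest:
    """Reproducibility record for a study run."""

    master_seed: int
    reps: int
    grid: dict
    rules: dict
    sampler: dict
    package_version: str = __version__
    numpy_version: str = np.__version__
    completed: dict = field(default_factory=dict)  # cell label -> rep count

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


def replicate_seed(master_seed: int, cell_index: int,
                   rep_index: int) -> np.random.SeedSequence:
    """Independent, reproducible stream for one replicate of one cell."""
    return np.random.SeedSequence(master_seed,
                                  spawn_key=(cell_index, rep_index))


def load_study_config(path) -> dict:
    """Read a YAML or JSON study configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def study_grid(study: dict) -> list[TrialConfig]:
    """Build the validated configuration grid described by a study dict."""
    grid = {**_DEFAULT_GRID, **study.get("grid", {})}
    rules = AdaptiveRuleConfig(**study.get("rules", {}))
    sampler = SamplerSettings(**study.get("sampler", {}))
    return build_grid(grid["scenarios"], grid["iccs"], grid["ns"],
                      grid["ks"], grid["adaptive"], rules=rules,
                      sampler=sampler)


def _result_row(result: TrialResult, master_seed: int, rep: int) -> dict:
    cfg = result.config
    row = {
        "cell": cfg.cell_label(),
        "cell_seed": cfg.seed,
        "rep": rep,
        "master_seed": master_seed,
        "scenario": cfg.scenario.scenario_id,
        "icc": cfg.icc,
        "n_per_cluster": cfg.n_per_cluster,
        "k_per_arm": cfg.k_per_arm,
        "adaptive": cfg.adaptive,
        "decision": result.decision.kind if result.decision else "",
        "dropped_arm": (result.decision.dropped_arm
                        if result.decision and result.decision.dropped_arm
                        else 0),
        "success": bool(result.success),
        "any_flagged": bool(result.any_flagged),
        "fit_failed": result.error is not None,
        "error": result.error or "",
    }
    for i, a in enumerate((1, 2, 3, 4)):
        row[f"clusters_arm{a}"] = result.clusters_recruited_per_arm[i]
    for a in (1, 2, 3, 4):
        row[f"p_best{a}"] = (result.final_p_best[a]
                             if result.final_p_best is not None else math.nan)
        row[f"interim_p_best{a}"] = (
            result.decision.p_best_at_interim[a]
            if result.decision is not None else math.nan)
    return row


def _run_replicate(config: TrialConfig, master_seed: int, rep: int) -> dict:
    result = run_trial(config, replicate_seed(master_seed, config.seed, rep))
    if result.error:
        logger.warning("cell %s rep %d: fit error: %s",
                       config.cell_label(), rep, result.error)
    else:
        logger.debug("cell %s rep %d: decision=%s success=%s",
                     config.cell_label(), rep,
                     result.decision.kind if result.decision else "final",
                     result.success)
    return _result_row(result, master_seed, rep)


def run_study(
    study: dict | str | Path,
    out_dir: str | Path,
    reps: int | None = None,
    master_seed: int | None = None,
    workers: int = 1,
    resume: bool = True,
) -> Path:
    """Run (or resume) every replicate of every grid cell of a study.

    ``study`` is a dict or a YAML/JSON path with optional keys
    ``master_seed``, ``reps``, ``grid`` (factor lists), ``rules`` and
    ``sampler``; explicit arguments override file values.  Writes
    per-cell raw CSV shards, an aggregated CSV, and a JSON manifest to
    ``out_dir`` and returns that directory.
    """
    if not isinstance(study, dict):
        study = load_study_config(study)
    reps = int(reps if reps is not None else study.get("reps", 1))
    master_seed = int(master_seed if master_seed is not None
                      else study.get("master_seed", 0))
    out = Path(out_dir)
    raw_dir = out / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)
    configs = study_grid(study)
    manifest = RunManifest(
        master_seed=master_seed, reps=reps,
        grid={**_DEFAULT_GRID, **study.get("grid", {})},
        rules=study.get("rules", {}), sampler=study.get("sampler", {}))

    for cfg in configs:
        shard = raw_dir / f"{cfg.cell_label()}.csv"
        done: set[int] = set()
        if resume and shard.exists():
            try:
                done = set(pd.read_csv(shard)["rep"].astype(int))
            except Exception:  # corrupt shard: redo the cell
                shard.unlink()
        todo = [r for r in range(reps) if r not in done]
        if todo:
            if workers > 1:
                from joblib import Parallel, delayed

                rows = Parallel(n_jobs=workers)(
                    delayed(_run_replicate)(cfg, master_seed, r) for r in todo)
            else:
                rows = [_run_replicate(cfg, master_seed, r) for r in todo]
            new = pd.DataFrame(rows)
            header = not shard.exists()
            new.to_csv(shard, mode="a", header=header, index=False)
        manifest.completed[cfg.cell_label()] = reps
        manifest.save(out / "manifest.json")
    report(out)
    return out


def _aggregate_raw(df: pd.DataFrame) -> pd.DataFrame:
    """Cell-level operating characteristics from raw replicate rows."""
    rows = []
    keys = ["scenario", "icc", "n_per_cluster", "k_per_arm", "adaptive"]
    for key, g in df.groupby(keys):
        n = len(g)
        p = g["success"].mean()
        row = dict(zip(keys, key))
        row.update({
            "n_reps": n,
            "success_proportion": p,
            "mcse": math.sqrt(p * (1 - p) / n),
            "futility_stop_proportion": (g["decision"] == "stop_futility").mean(),
            "continue_all_proportion": (g["decision"] == "continue_all").mean(),
            "convergence_flag_proportion": g["any_flagged"].mean(),
            "fit_failure_proportion": g["fit_failed"].mean(),
        })
        for arm in (2, 3, 4):
            row[f"drop_arm{arm}_proportion"] = (
                (g["decision"] == "drop_arm") & (g["dropped_arm"] == arm)
            ).mean()
        rows.append(row)
    return pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)


def report(results_dir: str | Path, figures: bool = False) -> dict[str, pd.DataFrame]:
    """Aggregate a results directory into summary tables (and figures).

    Emits ``aggregate.csv`` (one row per cell) and side-by-side
    adaptive-vs-fixed tables for power/type-1 error, decision
    frequencies, and convergence-flag proportions, each with Monte
    Carlo SE columns where applicable.  Missing cells yield a partial
    report with a warning.
    """
    out = Path(results_dir)
    raw_dir = out / "raw"
    shards = sorted(raw_dir.glob("*.csv")) if raw_dir.exists() else []
    if not shards:
        raise FileNotFoundError(f"no raw result shards under {raw_dir}")
    df = pd.concat([pd.read_csv(s) for s in shards], ignore_index=True)
    agg = _aggregate_raw(df)
    agg.to_csv(out / "aggregate.csv", index=False)

    keys = ["scenario", "icc", "n_per_cluster", "k_per_arm"]
    tables: dict[str, pd.DataFrame] = {"aggregate": agg}
    for metric in ("success_proportion", "mcse", "futility_stop_proportion",
                   "convergence_flag_proportion"):
        wide = agg.pivot_table(index=keys, columns="adaptive", values=metric)
        wide.columns = [("adaptive" if c else "fixed") for c in wide.columns]
        if "adaptive" not in wide.columns or "fixed" not in wide.columns:
            logger.warning("metric %s: only one design type present", metric)
        tables[metric] = wide.reset_index()
    tables["success_proportion"].to_csv(out / "power_type1.csv", index=False)

    decisions = agg[agg["adaptive"] == True]  # noqa: E712
    if len(decisions):
        cols = keys + ["n_reps", "continue_all_proportion",
                       "futility_stop_proportion"] + \
            [f"drop_arm{a}_proportion" for a in (2, 3, 4)]
        tables["decisions"] = decisions[cols].reset_index(drop=True)
        tables["decisions"].to_csv(out / "decisions.csv", index=False)
    else:
        logger.warning("no adaptive cells: decision table omitted")

    if figures:
        _figures(agg, out)
    return tables


def _figures(agg: pd.DataFrame, out: Path) -> None:
    """Proportion-vs-design-cell panels with MCSE error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, fname in (("success_proportion", "power.png"),
                          ("futility_stop_proportion", "futility.png")):
        fig, ax = plt.subplots(figsize=(10, 4))
        for adaptive, g in agg.groupby("adaptive"):
            g = g.sort_values(["scenario", "icc", "n_per_cluster", "k_per_arm"])
            labels = [f"s{r.scenario}/icc{r.icc:g}/n{r.n_per_cluster}"
                      f"/k{r.k_per_arm}" for r in g.itertuples()]
            ax.errorbar(labels, g[metric], yerr=g["mcse"], marker="o",
                        linestyle="none",
                        label="adaptive" if adaptive else "fixed")
        ax.set_ylabel(metric.replace("_", " "))
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / fname, dpi=120)
        plt.close(fig)
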