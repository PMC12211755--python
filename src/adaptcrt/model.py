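"""Posterior inference for the hierarchical trial model.

``fit_model`` draws from the posterior of the Bayesian hierarchical
logistic model (see :mod:`adaptcrt.nuts` for the model statement),
``prob_best`` converts posterior draws into per-arm probabilities of
being the best arm, and ``flag_convergence`` applies the convergence
screen used throughout the simulation study: a fit is flagged when any
non-reference treatment-arm parameter has rank-normalised split
R-hat > 1.05 or bulk/tail effective sample size below 400 (100 per
chain at the default 4 chains).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .design import SamplerSettings
from .dgm import ClusterDataset
from .nuts import nuts_chain

__all__ = [
    "PosteriorFit",
    "ConvergenceDiagnostics",
    "BestArmProbabilities",
    "FitError",
    "fit_model",
    "prob_best",
    "flag_convergence",
]

TREATMENT_PARAMS = ("theta2", "theta3", "theta4")
RHAT_LIMIT = 1.05
ESS_LIMIT = 400.0


def _diagnostic_fns():
    # arviz emits a refactor FutureWarning on import; keep it quiet here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az
    return az.rhat, az.ess


@dataclass(frozen=True)
class ConvergenceDiagnostics:
    """Per-parameter sampler diagnostics plus the study's binary flag."""

    r_hat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    flagged: bool
    n_divergent: int = 0
    n_maxdepth: int = 0

    def worst(self) -> dict[str, float]:
        keys = [k for k in TREATMENT_PARAMS if k in self.r_hat]
        return {
            "max_r_hat": max(self.r_hat[k] for k in keys),
            "min_ess_bulk": min(self.ess_bulk[k] for k in keys),
            "min_ess_tail": min(self.ess_tail[k] for k in keys),
        }


@dataclass(frozen=True)
class BestArmProbabilities:
    """Posterior probability, per arm (control first), of being best."""

    p_best: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p_best, dtype=float)
        if p.shape != (4,):
            raise ValueError("p_best must have exactly 4 entries")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("p_best entries must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"p_best must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "p_best", p)

    def __getitem__(self, arm: int) -> float:
        """Probability for 1-based arm index (1 = control)."""
        return float(self.p_best[arm - 1])


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one fitted trial dataset."""

    theta1_draws: np.ndarray          # (total_draws,) control log-odds
    contrast_draws: np.ndarray        # (total_draws, 3) theta2..theta4
    alpha_draws: np.ndarray           # (total_draws, K) cluster effects
    sigma_a_draws: np.ndarray         # (total_draws,)
    diagnostics: ConvergenceDiagnostics
    cluster_ids: np.ndarray = field(default_factory=lambda: np.empty(0))
    chains: int = 1
    retried: bool = False

    @property
    def n_draws(self) -> int:
        return self.theta1_draws.shape[0]

    def contrast_means(self) -> np.ndarray:
        return self.contrast_draws.mean(axis=0)

    def summary(self) -> dict:
        """Flat summary suitable for CSV/JSON serialisation."""
        out = {
            "theta1_mean": float(self.theta1_draws.mean()),
            "theta1_sd": float(self.theta1_draws.std()),
            "sigma_a_mean": float(self.sigma_a_draws.mean()),
            "flagged": self.diagnostics.flagged,
            "n_divergent": self.diagnostics.n_divergent,
        }
        for i, name in enumerate(TREATMENT_PARAMS):
            out[f"{name}_mean"] = float(self.contrast_draws[:, i].mean())
            out[f"{name}_sd"] = float(self.contrast_draws[:, i].std())
            out[f"{name}_r_hat"] = self.diagnostics.r_hat[name]
            out[f"{name}_ess_bulk"] = self.diagnostics.ess_bulk[name]
            out[f"{name}_ess_tail"] = self.diagnostics.ess_tail[name]
        return out


class FitError(RuntimeError):
    """Sampling failed; carries whatever diagnostics were computed."""

    def __init__(self, message: str,
                 diagnostics: ConvergenceDiagnostics | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


def flag_convergence(
    r_hat: Mapping[str, float],
    ess_bulk: Mapping[str, float],
    ess_tail: Mapping[str, float],
    n_divergent: int = 0,
    n_maxdepth: int = 0,
) -> ConvergenceDiagnostics:
    """Apply the convergence screen to per-parameter diagnostic values.

    Only the non-reference treatment-arm parameters (theta2..theta4)
    can trigger the flag; the intercept and cluster effects are recorded
    but ignored.  Thresholds are strict: R-hat must exceed 1.05, ESS
    must fall below 400.
    """
    for name in TREATMENT_PARAMS:
        for mapping, label in ((r_hat, "r_hat"), (ess_bulk, "ess_bulk"),
                               (ess_tail, "ess_tail")):
            if name not in mapping:
                raise ValueError(f"missing {label} for parameter {name}")
    flagged = any(
        r_hat[p] > RHAT_LIMIT
        or ess_bulk[p] < ESS_LIMIT
        or ess_tail[p] < ESS_LIMIT
        for p in TREATMENT_PARAMS
    )
    return ConvergenceDiagnostics(
        r_hat=dict(r_hat), ess_bulk=dict(ess_bulk), ess_tail=dict(ess_tail),
        flagged=flagged, n_divergent=int(n_divergent),
        n_maxdepth=int(n_maxdepth),
    )


def _run_chains(s, n, arm, sampler: SamplerSettings, rng: np.random.Generator,
                like_scale: float):
    K = s.shape[0]
    d = 5 + K
    per_chain = []
    n_div = 0
    n_maxdepth = 0
    for _ in range(sampler.chains):
        seed = int(rng.integers(0, 2 ** 31))
        x0 = rng.uniform(-2.0, 2.0, d)
        draws, lps, div, maxd = nuts_chain(
            seed, x0, s, n, arm, like_scale,
            sampler.theta_prior_scale, sampler.sigma_prior_scale,
            sampler.non_centered,
            sampler.warmup_per_chain, sampler.draws_per_chain,
            sampler.target_acceptance, sampler.max_treedepth)
        per_chain.append(draws)
        n_div += div
        n_maxdepth += maxd
    return np.stack(per_chain), n_div, n_maxdepth  # (chains, draws, d)


def _diagnose(chain_draws: np.ndarray, K: int, n_div: int,
              n_maxdepth: int) -> ConvergenceDiagnostics:
    rhat_fn, ess_fn = _diagnostic_fns()
    names = ["theta1", "theta2", "theta3", "theta4", "sigma_a"]
    cols = [0, 1, 2, 3, 4 + K]
    r_hat, ess_bulk, ess_tail = {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, c in zip(names, cols):
            arr = chain_draws[:, :, c]
            r_hat[name] = float(rhat_fn(arr))
            ess_bulk[name] = float(ess_fn(arr, method="bulk"))
            ess_tail[name] = float(ess_fn(arr, method="tail"))
    return flag_convergence(r_hat, ess_bulk, ess_tail, n_div, n_maxdepth)


def fit_model(
    data: ClusterDataset,
    sampler: SamplerSettings | None = None,
    rng: np.random.Generator | None = None,
    prior_only: bool = False,
) -> PosteriorFit:
    """Fit the hierarchical Bayesian logistic model to a trial dataset.

    Draws ``chains x draws_per_chain`` posterior samples via NUTS with
    the configured target acceptance, non-centered cluster effects by
    default, and per-chain seeds/inits taken from ``rng``.  A fit whose
    divergence count exceeds the configured cap, or that produces
    non-finite draws, is retried once with fresh sub-seeds and raises
    :class:`FitError` (carrying diagnostics) if it fails again.

    With ``prior_only`` the likelihood is removed and the priors are
    sampled, which is useful for validating the prior implementation.
    """
    sampler = sampler if sampler is not None else SamplerSettings()
    rng = rng if rng is not None else np.random.default_rng()
    if data.n_rows == 0:
        raise ValueError("empty dataset")
    ids, s, n, arm = data.cluster_summary()
    if ids.size < 2:
        raise ValueError("at least 2 clusters are required")
    like_scale = 0.0 if prior_only else 1.0
    K = ids.size

    last_diag = None
    for attempt in range(2):
        chain_draws, n_div, n_maxdepth = _run_chains(
            s, n, arm, sampler, rng, like_scale)
        bad = not np.isfinite(chain_draws).all()
        cap = sampler.divergence_cap_fraction * sampler.total_draws
        if bad:
            last_diag = None
            continue
        diag = _diagnose(chain_draws, K, n_div, n_maxdepth)
        last_diag = diag
        if n_div > cap:
            continue
        flat = chain_draws.reshape(-1, chain_draws.shape[-1])
        sigma = np.exp(flat[:, 4 + K])
        z = flat[:, 4:4 + K]
        alpha = sigma[:, None] * z if sampler.non_centered else z
        return PosteriorFit(
            theta1_draws=flat[:, 0].copy(),
            contrast_draws=flat[:, 1:4].copy(),
            alpha_draws=alpha,
            sigma_a_draws=sigma,
            diagnostics=diag,
            cluster_ids=ids,
            chains=sampler.chains,
            retried=attempt > 0,
        )
    raise FitError("sampler failed twice (non-finite draws or divergence "
                   "cap exceeded)", diagnostics=last_diag)


def prob_best(fit: PosteriorFit) -> BestArmProbabilities:
    """Per-draw argmax over the four arm-level effects.

    The control's linear predictor is theta1 and arm j > 1 has
    theta1 + theta_j, so the argmax over arms equals the argmax over the
    contrast vector (0, theta2, theta3, theta4) in every draw.  Ties go
    to the lowest arm index (a measure-zero event for continuous draws).
    """
    if fit.n_draws < 1:
        raise ValueError("fit has no draws")
    effects = np.column_stack([
        np.zeros(fit.n_draws), fit.contrast_draws])
    winners = np.argmax(effects, axis=1)
    counts = np.bincount(winners, minlength=4)
    return BestArmProbabilities(counts / fit.n_draws)
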