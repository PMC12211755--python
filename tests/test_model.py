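import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaptcrt import (
    BestArmProbabilities,
    PosteriorFit,
    SamplerSettings,
    fit_model,
    flag_convergence,
    prob_best,
    simulate_clusters,
)
from adaptcrt.dgm import scenario_to_log_odds
from adaptcrt.model import ConvergenceDiagnostics

from conftest import make_config


def fit_from_contrasts(contrasts):
    contrasts = np.atleast_2d(np.asarray(contrasts, dtype=float))
    n = contrasts.shape[0]
    diag = ConvergenceDiagnostics({}, {}, {}, flagged=False)
    return PosteriorFit(
        theta1_draws=np.zeros(n), contrast_draws=contrasts,
        alpha_draws=np.zeros((n, 1)), sigma_a_draws=np.zeros(n),
        diagnostics=diag)


def brute_force_p_best(contrasts):
    """Independent oracle: count per-draw argmax over arm-level effects."""
    counts = [0, 0, 0, 0]
    for row in contrasts:
        effects = [0.0, row[0], row[1], row[2]]
        best, best_val = 0, effects[0]
        for j in (1, 2, 3):
            if effects[j] > best_val:
                best, best_val = j, effects[j]
        counts[best] += 1
    return [c / len(contrasts) for c in counts]


class TestProbBest:
    def test_worked_example(self):
        draws = [(0.5, 1.0, 2.0), (-0.1, 0.2, 0.1), (0.3, 0.2, 0.1),
                 (-1, -2, -0.5), (0.1, 0.9, 1.5)]
        pb = prob_best(fit_from_contrasts(draws))
        assert pb.p_best == pytest.approx([0.2, 0.2, 0.2, 0.4])

    def test_dominant_arm(self):
        rng = np.random.default_rng(0)
        draws = np.abs(rng.normal(1, 0.2, (50, 3)))
        draws[:, 2] += 5.0  # arm 4 always largest and positive
        pb = prob_best(fit_from_contrasts(draws))
        assert pb.p_best == pytest.approx([0, 0, 0, 1])

    def test_single_draw_is_indicator(self):
        pb = prob_best(fit_from_contrasts([(0.5, 2.0, 1.0)]))
        assert pb.p_best == pytest.approx([0, 0, 1, 0])
        assert pb[3] == 1.0

    def test_control_wins_when_all_contrasts_negative(self):
        pb = prob_best(fit_from_contrasts([(-0.5, -2.0, -1.0)]))
        assert pb[1] == 1.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            draws = rng.normal(0, 2, (rng.integers(1, 30), 3))
            pb = prob_best(fit_from_contrasts(draws))
            assert pb.p_best == pytest.approx(brute_force_p_best(draws))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 40))
    def test_brute_force_equivalence_property(self, seed, n):
        draws = np.random.default_rng(seed).normal(0, 3, (n, 3))
        pb = prob_best(fit_from_contrasts(draws))
        assert pb.p_best == pytest.approx(brute_force_p_best(draws))
        assert pb.p_best.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError):
            prob_best(fit_from_contrasts(np.empty((0, 3))))


class TestBestArmProbabilities:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            BestArmProbabilities(np.array([0.5, 0.2, 0.2, 0.2]))

    def test_one_based_indexing(self):
        pb = BestArmProbabilities(np.array([0.1, 0.2, 0.3, 0.4]))
        assert pb[1] == 0.1 and pb[4] == 0.4


class TestFlagConvergence:
    CLEAN = {p: 1.0 for p in ("theta2", "theta3", "theta4")}
    BIG = {p: 3000.0 for p in ("theta2", "theta3", "theta4")}

    def test_all_clean(self):
        diag = flag_convergence(self.CLEAN, self.BIG, self.BIG)
        assert not diag.flagged

    def test_rhat_over_limit_flags(self):
        rhat = dict(self.CLEAN, theta3=1.051)
        assert flag_convergence(rhat, self.BIG, self.BIG).flagged

    def test_rhat_at_limit_does_not_flag(self):
        rhat = dict(self.CLEAN, theta3=1.05)
        assert not flag_convergence(rhat, self.BIG, self.BIG).flagged

    def test_ess_strict_boundary(self):
        ess = dict(self.BIG, theta2=399.0)
        assert flag_convergence(self.CLEAN, ess, self.BIG).flagged
        ess = dict(self.BIG, theta2=400.0)
        assert not flag_convergence(self.CLEAN, ess, self.BIG).flagged

    def test_tail_ess_also_screened(self):
        ess = dict(self.BIG, theta4=100.0)
        assert flag_convergence(self.CLEAN, self.BIG, ess).flagged

    def test_reference_parameter_ignored(self):
        rhat = dict(self.CLEAN, theta1=1.5)
        assert not flag_convergence(rhat, self.BIG, self.BIG).flagged

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError, match="theta4"):
            flag_convergence({"theta2": 1.0, "theta3": 1.0},
                             self.BIG, self.BIG)


class TestFitModel:
    def test_contract_draw_count_and_diagnostics(self, small_dataset):
        fit = fit_model(small_dataset, SamplerSettings(),
                        np.random.default_rng(0))
        assert fit.n_draws == 3000
        for p in ("theta2", "theta3", "theta4"):
            assert p in fit.diagnostics.r_hat
        assert (fit.sigma_a_draws >= 0).all()
        assert fit.alpha_draws.shape == (3000, small_dataset.n_clusters)

    def test_p_best_sums_to_one(self, small_dataset, fast_sampler):
        fit = fit_model(small_dataset, fast_sampler, np.random.default_rng(1))
        assert prob_best(fit).p_best.sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_large_data_symmetry(self):
        # under the null no arm dominates *on average*; a single dataset
        # can still have a clear sample leader, so average over replicates
        cfg = make_config(scenario_id=3, icc=0.05, n=50, k=50)
        mean_pb = np.zeros(4)
        n_reps = 6
        for r in range(n_reps):
            ss = np.random.SeedSequence(12, spawn_key=(r,))
            d_ss, f_ss = ss.spawn(2)
            data = simulate_clusters(cfg, {a: 50 for a in (1, 2, 3, 4)},
                                     np.random.default_rng(d_ss))
            fit = fit_model(data, SamplerSettings(),
                            np.random.default_rng(f_ss))
            mean_pb += prob_best(fit).p_best
        mean_pb /= n_reps
        assert mean_pb.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(0.05 <= p <= 0.55 for p in mean_pb)

    def test_empty_dataset_rejected(self, small_dataset):
        import pandas as pd
        from adaptcrt.dgm import ClusterDataset
        empty = ClusterDataset(small_dataset.data.iloc[:0].copy())
        with pytest.raises(ValueError):
            fit_model(empty)


def test_posterior_interval_calibration():
    """Central 90% intervals for the contrasts cover the generating values
    at close to nominal rate when the generative model and the analysis
    priors are not in conflict (no clustering, so the sigma_a hyperprior
    is uninformative about a latent scale that is truly zero)."""
    cfg = make_config(scenario_id=1, icc=0.0, n=25, k=5)
    _, beta = scenario_to_log_odds(cfg.scenario)
    n_reps = 200
    covered = np.zeros(3)
    for r in range(n_reps):
        ss = np.random.SeedSequence(2024, spawn_key=(r,))
        d_ss, f_ss = ss.spawn(2)
        data = simulate_clusters(cfg, {a: 5 for a in (1, 2, 3, 4)},
                                 np.random.default_rng(d_ss))
        fit = fit_model(data, cfg.sampler, np.random.default_rng(f_ss))
        lo = np.percentile(fit.contrast_draws, 5, axis=0)
        hi = np.percentile(fit.contrast_draws, 95, axis=0)
        covered += (lo <= beta) & (beta <= hi)
    pooled = covered.sum() / (3 * n_reps)
    assert 0.84 <= pooled <= 0.96
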