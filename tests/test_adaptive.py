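from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaptcrt import (
    AdaptiveRuleConfig,
    BestArmProbabilities,
    arm_drop_decision,
    futility_decision,
    interim_cluster_count,
    reallocate_clusters,
    run_trial,
)
from adaptcrt.adaptive import CONTINUE_ALL, DROP_ARM, STOP_FUTILITY, InterimDecision
import adaptcrt.adaptive as adaptive_mod

from conftest import make_config


def pb(control, a2, a3, a4):
    return BestArmProbabilities(np.array([control, a2, a3, a4]))


class TestInterimClusterCount:
    @pytest.mark.parametrize("k, frac, expected", [
        (5, 0.5, 3),    # interim at three clusters per arm
        (10, 0.5, 5),   # interim at five clusters per arm
        (7, 0.5, 4),    # ceil(3.5)
    ])
    def test_ceiling_rule(self, k, frac, expected):
        assert interim_cluster_count(k, frac) == expected

    def test_interim_must_precede_completion(self):
        with pytest.raises(ValueError):
            interim_cluster_count(2, 0.9)  # ceil(1.8) = 2 == k

    def test_too_few_clusters(self):
        with pytest.raises(ValueError):
            interim_cluster_count(1, 0.5)


class TestFutilityDecision:
    def test_all_below_threshold(self, rules):
        assert futility_decision(pb(0.18, 0.25, 0.28, 0.29), rules)

    def test_one_arm_at_or_above(self, rules):
        assert not futility_decision(pb(0.16, 0.25, 0.28, 0.31), rules)

    def test_strict_inequality_boundary(self, rules):
        assert not futility_decision(pb(0.50, 0.30, 0.10, 0.10), rules)

    def test_control_probability_ignored(self, rules):
        # control dominating does not matter: treatment arms decide
        assert futility_decision(pb(0.97, 0.01, 0.01, 0.01), rules)


class TestArmDropDecision:
    def test_single_candidate(self, rules):
        assert arm_drop_decision(pb(0.05, 0.04, 0.30, 0.61),
                                 (0.5, 1.0, 2.0), rules) == 2

    def test_lowest_probability_dropped(self, rules):
        assert arm_drop_decision(pb(0.05, 0.04, 0.03, 0.88),
                                 (0.5, 1.0, 2.0), rules) == 3

    def test_tie_broken_by_lowest_effect_estimate(self, rules):
        assert arm_drop_decision(pb(0.05, 0.04, 0.04, 0.87),
                                 (0.2, 0.1, 2.0), rules) == 3

    def test_no_candidate(self, rules):
        assert arm_drop_decision(pb(0.1, 0.2, 0.3, 0.4),
                                 (0.5, 1.0, 2.0), rules) is None

    def test_control_never_dropped(self, rules):
        # control has the smallest probability of best; still untouchable
        assert arm_drop_decision(pb(0.01, 0.09, 0.4, 0.5),
                                 (0.5, 1.0, 2.0), rules) is None


class TestReallocateClusters:
    def test_even_split_four_arms(self):
        alloc = reallocate_clusters(5, 3, {1, 2, 3, 4},
                                    np.random.default_rng(0))
        assert alloc == {1: 2, 2: 2, 3: 2, 4: 2}

    def test_three_arms_k10(self):
        alloc = reallocate_clusters(10, 5, {1, 3, 4},
                                    np.random.default_rng(1))
        assert sorted(alloc.values()) == [6, 7, 7]
        assert sum(alloc.values()) == 20

    def test_three_arms_k5(self):
        alloc = reallocate_clusters(5, 3, {1, 2, 4}, np.random.default_rng(2))
        assert sorted(alloc.values()) == [2, 3, 3]

    def test_remainder_assignment_is_random_but_seeded(self):
        a1 = reallocate_clusters(5, 3, {1, 2, 4}, np.random.default_rng(3))
        a2 = reallocate_clusters(5, 3, {1, 2, 4}, np.random.default_rng(3))
        assert a1 == a2
        winners = Counter()
        for s in range(200):
            alloc = reallocate_clusters(5, 3, {1, 2, 4},
                                        np.random.default_rng(s))
            for arm, c in alloc.items():
                if c == 3:
                    winners[arm] += 1
        assert set(winners) == {1, 2, 4}  # every arm sometimes gets extra

    def test_control_must_remain(self):
        with pytest.raises(ValueError):
            reallocate_clusters(5, 3, {2, 3, 4}, np.random.default_rng(0))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(2, 30), st.sampled_from([[1, 2, 3, 4], [1, 2, 3],
                                                [1, 2, 4], [1, 3, 4]]),
           st.integers(0, 2 ** 31 - 1))
    def test_budget_conserved_and_balanced(self, k, arms, seed):
        ic = interim_cluster_count(k, 0.5)
        alloc = reallocate_clusters(k, ic, arms, np.random.default_rng(seed))
        assert sum(alloc.values()) == 4 * k - 4 * ic
        assert max(alloc.values()) - min(alloc.values()) <= 1


class _ScriptedFit:
    """Stub posterior fit driving run_trial through scripted decisions."""

    def __init__(self, contrasts):
        self._means = np.asarray(contrasts, dtype=float)
        self.diagnostics = None

    def contrast_means(self):
        return self._means


def _script_interims(monkeypatch, p_best_seq, means=(0.5, 1.0, 2.0)):
    queue = list(p_best_seq)
    monkeypatch.setattr(adaptive_mod, "_safe_fit",
                        lambda data, config, rng: _ScriptedFit(means))
    monkeypatch.setattr(adaptive_mod, "prob_best",
                        lambda fit: queue.pop(0))


class TestRunTrialRuleComposition:
    def test_futility_stops_whole_trial(self, monkeypatch):
        cfg = make_config(adaptive=True, n=2, k=5)
        _script_interims(monkeypatch, [pb(0.4, 0.2, 0.2, 0.2)])
        res = run_trial(cfg, np.random.SeedSequence(0))
        assert res.decision.kind == STOP_FUTILITY
        assert not res.success
        assert sum(res.clusters_recruited_per_arm) == 4 * 3

    def test_futility_takes_precedence_over_drop(self, monkeypatch):
        # arm 2 qualifies for dropping AND all arms are futile
        cfg = make_config(adaptive=True, n=2, k=5)
        _script_interims(monkeypatch, [pb(0.71, 0.01, 0.14, 0.14)])
        res = run_trial(cfg, np.random.SeedSequence(0))
        assert res.decision.kind == STOP_FUTILITY
        assert res.decision.dropped_arm is None

    def test_drop_freezes_arm_and_conserves_budget(self, monkeypatch):
        cfg = make_config(adaptive=True, n=2, k=5)
        _script_interims(monkeypatch,
                         [pb(0.09, 0.01, 0.4, 0.5), pb(0.1, 0.1, 0.3, 0.5)])
        res = run_trial(cfg, np.random.SeedSequence(0))
        assert res.decision.kind == DROP_ARM
        assert res.decision.dropped_arm == 2
        assert res.clusters_recruited_per_arm[1] == 3  # frozen at interim
        assert sum(res.clusters_recruited_per_arm) == 4 * 5

    def test_continue_all(self, monkeypatch):
        cfg = make_config(adaptive=True, n=2, k=5)
        _script_interims(monkeypatch,
                         [pb(0.1, 0.2, 0.3, 0.4), pb(0.0, 0.0, 0.04, 0.96)])
        res = run_trial(cfg, np.random.SeedSequence(0))
        assert res.decision.kind == CONTINUE_ALL
        assert res.clusters_recruited_per_arm == (5, 5, 5, 5)
        assert res.success  # p_best4 = 0.96 >= 0.95

    def test_decision_invariants(self):
        with pytest.raises(ValueError):
            InterimDecision(DROP_ARM, 1, pb(0.25, 0.25, 0.25, 0.25), None)
        with pytest.raises(ValueError):
            InterimDecision(CONTINUE_ALL, 2, pb(0.25, 0.25, 0.25, 0.25), None)


class TestRunTrialIntegration:
    def test_fixed_trial_contract(self, fast_sampler):
        cfg = make_config(scenario_id=1, icc=0.05, n=5, k=3,
                          sampler=fast_sampler)
        res = run_trial(cfg, np.random.SeedSequence(1))
        assert res.decision is None
        assert res.clusters_recruited_per_arm == (3, 3, 3, 3)
        assert res.final_p_best.p_best.sum() == pytest.approx(1.0, abs=1e-12)

    def test_adaptive_trial_budget_and_control_retention(self, fast_sampler):
        cfg = make_config(scenario_id=2, icc=0.1, n=5, k=5, adaptive=True,
                          sampler=fast_sampler)
        for rep in range(3):
            res = run_trial(cfg, np.random.SeedSequence(10, spawn_key=(rep,)))
            counts = res.clusters_recruited_per_arm
            assert counts[0] >= 3  # control never dropped
            if res.decision.kind == STOP_FUTILITY:
                assert sum(counts) == 4 * 3
                assert not res.success
            else:
                assert sum(counts) == 4 * 5

    def test_seed_determinism(self, fast_sampler):
        cfg = make_config(scenario_id=2, icc=0.1, n=5, k=5, adaptive=True,
                          sampler=fast_sampler)
        r1 = run_trial(cfg, np.random.SeedSequence(77))
        r2 = run_trial(cfg, np.random.SeedSequence(77))
        assert r1.decision.kind == r2.decision.kind
        assert r1.success == r2.success
        assert r1.clusters_recruited_per_arm == r2.clusters_recruited_per_arm
        if r1.final_p_best is not None:
            assert np.array_equal(r1.final_p_best.p_best,
                                  r2.final_p_best.p_best)

    def test_disabled_rules_never_fire(self, fast_sampler, monkeypatch):
        # with thresholds at ~0 the adaptive trial degenerates to a fixed
        # design with a mid-trial refit
        rules = AdaptiveRuleConfig(drop_threshold=1e-12,
                                   futility_threshold=1e-9)
        cfg = make_config(scenario_id=2, icc=0.1, n=5, k=5, adaptive=True,
                          rules=rules, sampler=fast_sampler)
        res = run_trial(cfg, np.random.SeedSequence(5))
        assert res.decision.kind == CONTINUE_ALL
        assert res.clusters_recruited_per_arm == (5, 5, 5, 5)
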