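import numpy as np
import pytest

from adaptcrt import (
    AdaptiveRuleConfig,
    SamplerSettings,
    TrialConfig,
    TrialScenario,
    simulate_clusters,
)


@pytest.fixture(scope="session")
def rules():
    return AdaptiveRuleConfig()


@pytest.fixture(scope="session")
def default_sampler():
    return SamplerSettings()


@pytest.fixture(scope="session")
def fast_sampler():
    """Shorter chains for tests that exercise plumbing, not diagnostics."""
    return SamplerSettings(chains=2, warmup_per_chain=200, draws_per_chain=250)


def make_config(scenario_id=1, icc=0.05, n=5, k=5, adaptive=False, **kwargs):
    return TrialConfig(
        scenario=TrialScenario.from_id(scenario_id), icc=icc,
        n_per_cluster=n, k_per_arm=k, adaptive=adaptive, **kwargs)


@pytest.fixture
def small_dataset():
    cfg = make_config(scenario_id=1, icc=0.1, n=10, k=2)
    rng = np.random.default_rng(7)
    return simulate_clusters(cfg, {a: 2 for a in (1, 2, 3, 4)}, rng)
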