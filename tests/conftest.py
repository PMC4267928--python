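import numpy as np
import pytest
from hypothesis import settings

from gpaccuracy.config import ScenarioConfig
from gpaccuracy.simulate import (generate_alpha_design,
                                 simulate_breeding_values,
                                 simulate_marker_matrix, simulate_trial)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A scaled-down scenario for orchestration tests (fast to analyze)."""
    return ScenarioConfig(
        scenario_id=1, n_genotypes=40, n_markers=30,
        marker_variance=0.2019, error_variance=48.6728, error_sd=6.977,
        block_variance=12.1682, n_replicates=2, block_size=8,
        outlier_multiplier=5, n_datasets=3, seed=777)


def make_trial(n=30, q=20, marker_variance=0.3, block_variance=3.0,
               error_variance=10.0, r=2, block_size=6, seed=0,
               replicate_effects=None, mu=0.0):
    ss = np.random.SeedSequence(seed)
    s1, s2, s3, s4 = ss.spawn(4)
    markers = simulate_marker_matrix(n, q, seed=np.random.default_rng(s1))
    truth = simulate_breeding_values(markers, marker_variance,
                                     seed=np.random.default_rng(s2))
    design = generate_alpha_design(n, r, block_size,
                                   seed=np.random.default_rng(s3))
    trial = simulate_trial(design, truth, mu=mu,
                           replicate_effects=replicate_effects,
                           block_variance=block_variance,
                           error_variance=error_variance,
                           seed=np.random.default_rng(s4))
    return markers, trial


@pytest.fixture
def trial_and_markers():
    return make_trial()
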