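import numpy as np
import pytest

from chronnectome import WindowConfig, fc_series, postprocess_timecourses
from chronnectome import synthetic as syn


@pytest.fixture(scope="session")
def small_states():
    """Two well-separated 16-component states (sparse vs dense)."""
    blocks = [(1, 2, 3, 4), (5, 6, 7, 8), (9, 10, 11, 12), (13, 14, 15, 16)]
    sparse = syn.make_state_covariances(16, blocks, within_strength=0.2)
    dense = syn.make_state_covariances(
        16, blocks, within_strength=0.55,
        between_strengths={(1, 2): 0.35, (1, 3): -0.3}, noise_floor=0.05,
    )
    return [syn.StateSpec(1, sparse, "sparse"), syn.StateSpec(2, dense, "dense")]


@pytest.fixture(scope="session")
def small_groups():
    a = syn.GroupSpec("slow", 4, *syn._two_state_chain(0.30, 0.04))
    b = syn.GroupSpec("fast", 4, *syn._two_state_chain(0.42, 0.10))
    return [a, b]


@pytest.fixture(scope="session")
def small_cohort(small_states, small_groups):
    cohort, truth = syn.simulate_cohort(
        small_groups, small_states, T=150, TR=2.5, seed=11
    )
    truth.windowed(22, 1)
    return cohort, truth


@pytest.fixture(scope="session")
def small_window_config():
    return WindowConfig(lambda_grid=(0.1,), lambda_reps=1)


@pytest.fixture(scope="session")
def small_fc(small_cohort, small_window_config):
    """Windowed FC series for the 8-subject desk cohort (fixed penalty)."""
    cohort, _ = small_cohort
    return [
        fc_series(postprocess_timecourses(tc), small_window_config,
                  lambda_penalty=0.1)
        for tc in cohort
    ]
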