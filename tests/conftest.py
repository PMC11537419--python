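"""Shared fixtures: small simulated cohorts, processed tables.

Session-scoped so the expensive simulation/processing runs once for the
whole suite.
"""

import numpy as np
import pytest

from gazeshelf import (
    AgentPolicy,
    GeneratorConfig,
    process_sessions,
    process_trial,
    simulate_session,
)


@pytest.fixture(scope="session")
def clean_session():
    """One noise-free subject (ground-truth recovery tests)."""
    cfg = GeneratorConfig(noise_sd_deg=0.0)
    return cfg, simulate_session(cfg, n_subjects=1, policy=AgentPolicy("greedy_optimal"), seed=42)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Four noisy subjects driven by the spatial heuristic agent."""
    cfg = GeneratorConfig()
    sessions = simulate_session(
        cfg, n_subjects=4, policy=AgentPolicy("spatial_heuristic"), seed=3
    )
    return cfg, sessions


@pytest.fixture(scope="session")
def processed(noisy_cohort):
    cfg, sessions = noisy_cohort
    return process_sessions(sessions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
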