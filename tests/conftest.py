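import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from redecision.agent import (
    AgentParams,
    SessionConfig,
    default_cohort_params,
    simulate_cohort,
    simulate_session,
)
from redecision.glm import TimingConfig, build_design, build_schedule


@pytest.fixture(scope="session")
def small_cohort():
    """8 participants x 3 sessions x 2 tasks, compact runs; reused read-only."""
    rng = np.random.default_rng(42)
    params = default_cohort_params(8, rng)
    cfg = SessionConfig(n_runs=2, task_trials_per_run=60, control_trials_per_run=10)
    return simulate_cohort(params, 3, rng, config=cfg)


@pytest.fixture(scope="session")
def run_table():
    """One default 4-run session (30 task + 10 control per run)."""
    return simulate_session(AgentParams(), SessionConfig(), 7)


@pytest.fixture(scope="session")
def one_run_design(run_table):
    """Schedule and convolved design for the first run of the session."""
    first = run_table[run_table["run"] == 0]
    schedule = build_schedule(first, TimingConfig())
    design = build_design(schedule, tr=2.0)
    return schedule, design
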