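"""Generative observer for decision-redecision trials.

A signal-detection observer with a separate, noisy second-order readout:

* Phase 1 (initial decision, 4-alternative collapsed to correct/incorrect
  with a 0.25 floor): latent evidence ``e1 ~ N(d(L), 1)`` where ``d(L)`` is
  calibrated so that ``P(e1 > 0)`` equals the logistic psychometric function
  ``a(L) = 0.25 + 0.75 / (1 + exp((L - m)/s))`` over difficulty levels
  ``L = 1..10``; the choice is correct iff ``e1 > 0``.  The metacognitive
  system receives a noisy copy of the decision evidence on the correctness
  axis, ``x1 = e1 + N(0, sigma_meta)`` (equivalently, the evidence magnitude
  signed by correctness), and reports confidence 1-4 by binning ``x1`` at
  three criteria straddling zero; decision uncertainty is
  ``u = 5 - confidence``.  Choice RT increases linearly with uncertainty.

* Phase 2 (redecision on the same stimulus): a fresh evidence sample with
  gain-improved quality drives the second choice, ``e2 ~ N(d2, 1)`` with
  ``d2 = g * d`` when ``d >= 0`` and ``d / g`` when ``d < 0`` (the gain
  ``g >= 1`` moves the drift toward the true direction at every level, so
  per-level accuracy never decreases and equals phase 1 at ``g = 1``).  The
  second confidence reads the combined evidence
  ``x2 = (e1 + e2) / sqrt(2) + N(0, sigma_meta)``.  By construction the
  expected uncertainty reduction grows with initial uncertainty and the
  accuracy improvement grows with the gain.

The meta-noise ``sigma_meta`` is the single knob for metacognitive
sensitivity: 0 gives near-perfect error detection (type-2 AUC -> 1), large
values make confidence uninformative (AUC -> 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .staircase import StaircaseState, staircase_update

__all__ = [
    "AgentParams",
    "SessionConfig",
    "TRIAL_COLUMNS",
    "psychometric_accuracy",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "default_cohort_params",
]

#: trial-table schema (one row per decision-redecision trial)
TRIAL_COLUMNS = [
    "participant",
    "task",
    "session",
    "run",
    "trial",
    "condition",
    "difficulty_level",
    "choice1",
    "correct1",
    "conf1",
    "u1",
    "rt1",
    "choice2",
    "correct2",
    "conf2",
    "u2",
    "rt2",
    "delta_u",
]

#: accuracy assumed on control trials (100% coherence / single-given grid)
CONTROL_ACCURACY = 0.97


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated observer (per task)."""

    m: float = 5.0          # psychometric midpoint level (training converges near 5)
    s: float = 1.2          # psychometric slope (levels)
    sigma_meta: float = 0.7  # second-order readout noise (sd)
    criteria: tuple[float, float, float] = (-0.4, 0.4, 1.2)
    rt_base: float = 0.6    # s
    rt_slope: float = 0.22  # s per uncertainty unit
    rt_sd: float = 0.25     # s
    redecision_gain: float = 1.6  # evidence multiplier in phase 2, >= 1
    lapse: float = 0.0      # in [0, 0.1]

    def __post_init__(self) -> None:
        c1, c2, c3 = self.criteria
        if not c1 < c2 < c3:
            raise ValueError("confidence criteria must be strictly increasing")
        if self.sigma_meta < 0 or self.rt_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.redecision_gain < 1:
            raise ValueError("redecision_gain must be >= 1")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")


@dataclass(frozen=True)
class SessionConfig:
    task: str = "sudoku"
    n_runs: int = 4
    task_trials_per_run: int = 30
    control_trials_per_run: int = 10
    staircase: bool = True
    start_level: int = 5
    fixed_level: Optional[int] = None  # used when staircase is off

    def __post_init__(self) -> None:
        if self.task not in ("sudoku", "rdm"):
            raise ValueError("task must be 'sudoku' or 'rdm'")
        if min(self.n_runs, self.task_trials_per_run) < 1:
            raise ValueError("need at least one run with one task trial")
        if self.control_trials_per_run < 0:
            raise ValueError("control_trials_per_run must be >= 0")
        if not self.staircase and self.fixed_level is None:
            raise ValueError("fixed_level is required when the staircase is off")


def psychometric_accuracy(level, m: float, s: float):
    """Initial-decision accuracy at a difficulty level: 0.25 + 0.75 logistic."""
    level = np.asarray(level, dtype=float)
    return 0.25 + 0.75 / (1.0 + np.exp((level - m) / s))


def _evidence_mean(accuracy: float) -> float:
    # calibrate N(d, 1) so that P(e > 0) matches the psychometric accuracy
    return float(norm.ppf(accuracy))


def _bin_confidence(x: float, criteria: Sequence[float]) -> int:
    return 1 + int(np.searchsorted(criteria, x, side="right"))


def simulate_trial(
    agent: AgentParams,
    level: Optional[int],
    task: str,
    rng: np.random.Generator | int,
) -> dict:
    """Simulate one decision-redecision trial; ``level=None`` means control."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    is_control = level is None
    if is_control:
        acc = CONTROL_ACCURACY
    else:
        acc = float(psychometric_accuracy(level, agent.m, agent.s))
    d = _evidence_mean(acc)

    e1 = rng.normal(d, 1.0)
    correct1 = e1 > 0
    if agent.lapse > 0 and rng.random() < agent.lapse:
        correct1 = rng.random() < 0.25
        e1 = rng.normal(0.0, 1.0)
    x1 = e1 + rng.normal(0.0, agent.sigma_meta)
    conf1 = _bin_confidence(x1, agent.criteria)
    u1 = 5 - conf1
    rt1 = float(np.clip(agent.rt_base + agent.rt_slope * u1 + rng.normal(0, agent.rt_sd), 0.2, 2.0))

    g = agent.redecision_gain
    d2 = g * d if d >= 0 else d / g
    e2 = rng.normal(d2, 1.0)
    correct2 = e2 > 0
    x2 = (e1 + e2) / np.sqrt(2.0) + rng.normal(0.0, agent.sigma_meta)
    conf2 = _bin_confidence(x2, agent.criteria)
    u2 = 5 - conf2
    rt2 = float(np.clip(agent.rt_base + agent.rt_slope * u2 + rng.normal(0, agent.rt_sd), 0.2, 2.0))

    # option identities: the correct option index is uniform over 4; an
    # erroneous choice is uniform over the three distractors
    correct_option = int(rng.integers(0, 4))
    def _choice(correct: bool) -> int:
        if correct:
            return correct_option
        return int((correct_option + 1 + rng.integers(0, 3)) % 4)

    return {
        "task": task,
        "condition": "control" if is_control else "task",
        "difficulty_level": np.nan if is_control else int(level),
        "choice1": _choice(bool(correct1)),
        "correct1": int(correct1),
        "conf1": conf1,
        "u1": u1,
        "rt1": rt1,
        "choice2": _choice(bool(correct2)),
        "correct2": int(correct2),
        "conf2": conf2,
        "u2": u2,
        "rt2": rt2,
        "delta_u": u1 - u2,
    }


def simulate_session(
    agent: AgentParams,
    config: SessionConfig,
    rng: np.random.Generator | int,
    participant: int = 0,
    session: int = 0,
) -> pd.DataFrame:
    """Simulate one session (``n_runs`` runs of interleaved task/control trials).

    The staircase is driven by initial-decision correctness of task trials
    only; control trials are interleaved at random positions within each run.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    state = StaircaseState(level=config.start_level)
    rows = []
    for run in range(config.n_runs):
        n_task, n_ctrl = config.task_trials_per_run, config.control_trials_per_run
        is_task = np.ones(n_task + n_ctrl, dtype=bool)
        if n_ctrl:
            is_task[rng.choice(n_task + n_ctrl, size=n_ctrl, replace=False)] = False
        for t, task_trial in enumerate(is_task):
            if task_trial:
                level = state.level if config.staircase else config.fixed_level
                rec = simulate_trial(agent, level, config.task, rng)
                if config.staircase:
                    state = staircase_update(state, bool(rec["correct1"]))
            else:
                rec = simulate_trial(agent, None, config.task, rng)
            rec.update(participant=participant, session=session, run=run, trial=t)
            rows.append(rec)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def default_cohort_params(
    n_participants: int,
    rng: np.random.Generator | int,
    tasks: Sequence[str] = ("sudoku", "rdm"),
) -> dict[int, dict[str, AgentParams]]:
    """Draw per-participant, per-task observer parameters.

    Emulates the behavioural structure of the cohort: metacognitive
    sensitivity (``sigma_meta``) and confidence-criterion placement are
    stable traits shared across tasks and sessions, whereas the redecision
    gain (the accuracy-change propensity) is drawn independently per task,
    so uncertainty sensitivity is reliable across tasks while accuracy
    change is not.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    params: dict[int, dict[str, AgentParams]] = {}
    for p in range(n_participants):
        sigma = float(rng.uniform(0.45, 1.5))
        shift = float(rng.normal(0.0, 0.25))
        crit = tuple(c + shift for c in AgentParams.criteria)
        base = AgentParams(sigma_meta=sigma, criteria=crit,
                           rt_base=float(rng.normal(0.6, 0.05)))
        params[p] = {
            task: replace(base, redecision_gain=float(rng.uniform(1.0, 2.8)))
            for task in tasks
        }
    return params


def simulate_cohort(
    params: dict[int, dict[str, AgentParams]],
    sessions_per_participant: int,
    rng: np.random.Generator | int,
    config: SessionConfig | None = None,
) -> pd.DataFrame:
    """Simulate a cohort: every participant x session x task, tidy long format."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if len(params) < 2:
        raise ValueError("need at least 2 participants for cohort analyses")
    frames = []
    for participant, per_task in sorted(params.items()):
        for session in range(sessions_per_participant):
            for task, agent in per_task.items():
                cfg = (config or SessionConfig())
                cfg = replace(cfg, task=task)
                frames.append(
                    simulate_session(agent, cfg, rng, participant=participant, session=session)
                )
    return pd.concat(frames, ignore_index=True)
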