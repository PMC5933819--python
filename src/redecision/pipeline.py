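"""End-to-end pipeline: simulate -> analyze -> GLM demo, with one run log.

A single top-level seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` spawning, so each stage can be rerun
independently and the whole pipeline is reproducible bit-for-bit.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agent import AgentParams, SessionConfig, default_cohort_params, simulate_cohort
from .config import RunConfig
from .connectivity import ppi_design, ppi_fit, trialwise_connectivity
from .glm import TimingConfig, build_design, build_schedule, fit_glm, simulate_bold, vif
from .io import export_schedule_ev3, write_connectivity, write_trial_table
from .metrics import summarize_cohort

__all__ = ["stage_seeds", "run_pipeline"]

_STAGES = ("simulate", "analyze", "glm")


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


def _timing_from_config(config: RunConfig) -> TimingConfig:
    t = config.timing
    return TimingConfig(cue=t.cue, stimulus=t.stimulus, choice=t.choice,
                        confidence=t.confidence, redecision=t.redecision,
                        choice2=t.choice2, confidence2=t.confidence2, iti=t.iti)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run simulate -> analyze -> glm-demo and write all artifacts.

    Outputs: ``trials.csv``, ``metrics_per_session.csv``,
    ``metrics_per_participant.csv``, ``reliability.json``, ``design_vif.json``,
    ``glm_fit.csv``, ``ppi.json``, ``connectivity_*.csv``, EV text files, and
    ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    log: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }

    def _stamp(stage: str) -> None:
        log["stages"].append(
            {"stage": stage, "time": _dt.datetime.now().isoformat(timespec="seconds")}
        )

    # --- simulate -----------------------------------------------------------
    rng = np.random.default_rng(seeds["simulate"])
    a = config.agent
    base = AgentParams(m=a.m, s=a.s, sigma_meta=a.sigma_meta, criteria=a.criteria,
                       rt_base=a.rt_base, rt_slope=a.rt_slope, rt_sd=a.rt_sd,
                       redecision_gain=a.redecision_gain, lapse=a.lapse)
    params = default_cohort_params(config.n_participants, rng)
    # the config's agent block sets the cohort's shared psychometric scaffold
    params = {
        p: {task: replace(ag, m=base.m, s=base.s) for task, ag in d.items()}
        for p, d in params.items()
    }
    session_cfg = SessionConfig(
        task=config.task, n_runs=config.runs,
        task_trials_per_run=config.task_trials_per_run,
        control_trials_per_run=config.control_trials_per_run,
        staircase=config.staircase, start_level=config.start_level,
        fixed_level=config.fixed_level,
    )
    cohort = simulate_cohort(params, config.sessions, rng, config=session_cfg)
    write_trial_table(cohort, out / "trials.csv")
    _stamp("simulate")

    # --- analyze ------------------------------------------------------------
    summary = summarize_cohort(cohort)
    summary.per_session.to_csv(out / "metrics_per_session.csv", index=False)
    summary.per_participant.to_csv(out / "metrics_per_participant.csv", index=False)
    with open(out / "reliability.json", "w") as fh:
        json.dump(summary.reliability, fh, indent=2, sort_keys=True)
    _stamp("analyze")

    # --- glm demo: schedule -> design -> simulate BOLD -> fit -> PPI -> FC ---
    rng_glm = np.random.default_rng(seeds["glm"])
    timing = _timing_from_config(config)
    first = cohort[
        (cohort["participant"] == cohort["participant"].min())
        & (cohort["session"] == cohort["session"].min())
        & (cohort["task"] == config.task)
        & (cohort["run"] == 0)
    ]
    schedule = build_schedule(first, timing)
    export_schedule_ev3(schedule, out / "ev")
    design = build_design(schedule, tr=config.glm.tr,
                          modulators=config.glm.orth_order)
    true_betas = np.zeros(design.values.shape[1])
    true_betas[design.labels.index("decision")] = 1.0
    true_betas[design.labels.index("post_decision")] = 0.8
    true_betas[design.labels.index("post_x_u1")] = 0.5
    y = simulate_bold(design, true_betas, sigma=1.0, rho=0.3, rng=rng_glm)
    fit = fit_glm(y, design)
    pd.DataFrame({"beta": fit.beta, "se": fit.se, "t": fit.tvalues}).to_csv(
        out / "glm_fit.csv"
    )
    with open(out / "design_vif.json", "w") as fh:
        json.dump({k: (None if np.isinf(v) else v) for k, v in fit.vif.items()},
                  fh, indent=2, sort_keys=True)

    task_ev = schedule.condition("task")
    u1 = task_ev["u1"].to_numpy()
    seed_series = simulate_bold(design, true_betas, sigma=1.0, rho=0.3, rng=rng_glm)
    ppi = ppi_design(seed_series, u1, schedule, tr=config.glm.tr)
    coupling = ppi_fit(y, ppi)
    with open(out / "ppi.json", "w") as fh:
        json.dump({k: float(v) for k, v in coupling.items()}, fh, indent=2)

    rois = {
        "roi_a": y,
        "roi_b": simulate_bold(design, true_betas, sigma=1.0, rho=0.3, rng=rng_glm),
    }
    mats = trialwise_connectivity(rois, schedule, tr=config.glm.tr)
    write_connectivity(mats, out)
    _stamp("glm")

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out
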