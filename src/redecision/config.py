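"""Run configuration: schema-validated JSON with strict unknown-key rejection."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "AgentBlock", "TimingBlock", "GLMBlock", "load_config"]


class AgentBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    m: float = 5.0
    s: float = 1.2
    sigma_meta: float = Field(0.7, ge=0)
    criteria: tuple[float, float, float] = (-0.4, 0.4, 1.2)
    rt_base: float = Field(0.6, gt=0)
    rt_slope: float = 0.22
    rt_sd: float = Field(0.25, ge=0)
    redecision_gain: float = Field(1.6, ge=1)
    lapse: float = Field(0.0, ge=0, le=0.1)


class TimingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cue: float = Field(1.0, gt=0)
    stimulus: float = Field(2.0, gt=0)
    choice: float = Field(2.0, gt=0)
    confidence: float = Field(2.0, gt=0)
    redecision: float = Field(4.0, gt=0)
    choice2: float = Field(2.0, gt=0)
    confidence2: float = Field(2.0, gt=0)
    iti: float = Field(2.0, ge=0)


class GLMBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tr: float = Field(2.0, gt=0)
    orth_order: tuple[str, ...] = ("u1", "rt", "delta_u")
    hrf_peak: float = Field(6.0, gt=0)
    hrf_undershoot: float = Field(16.0, gt=0)
    hrf_ratio: float = Field(6.0, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    task: str = "sudoku"
    n_participants: int = Field(4, ge=2)
    sessions: int = Field(1, ge=1)
    runs: int = Field(4, ge=1)
    task_trials_per_run: int = Field(30, ge=1)
    control_trials_per_run: int = Field(10, ge=0)
    staircase: bool = True
    start_level: int = Field(5, ge=1, le=10)
    fixed_level: int | None = Field(None, ge=1, le=10)
    seed: int
    agent: AgentBlock = AgentBlock()
    timing: TimingBlock = TimingBlock()
    glm: GLMBlock = GLMBlock()

    @model_validator(mode="after")
    def _check(self):
        if self.task not in ("sudoku", "rdm"):
            raise ValueError("task must be 'sudoku' or 'rdm'")
        if not self.staircase and self.fixed_level is None:
            raise ValueError("fixed_level required when staircase is off")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        return RunConfig.model_validate(json.load(fh))
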