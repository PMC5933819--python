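"""Trial-table and schedule I/O with schema validation."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .agent import TRIAL_COLUMNS
from .glm import EventSchedule

__all__ = [
    "TableValidationError",
    "read_trial_table",
    "write_trial_table",
    "export_schedule_ev3",
    "write_connectivity",
]


class TableValidationError(ValueError):
    def __init__(self, message: str, column: str | None = None, n_rejected: int = 0):
        super().__init__(message)
        self.column = column
        self.n_rejected = n_rejected


_INT_COLS = ["participant", "session", "run", "trial",
             "choice1", "correct1", "conf1", "u1",
             "choice2", "correct2", "conf2", "u2", "delta_u"]


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trial_table(path, drop_invalid: bool = True) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    Raises :class:`TableValidationError` naming the first missing column.
    Rows violating the row-level invariants (confidence outside 1-4,
    u != 5 - conf, RT outside (0, 2]) are dropped with the count recorded on
    the returned frame's ``attrs['n_rejected']`` (or raise when
    ``drop_invalid`` is false).
    """
    df = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise TableValidationError(f"missing required column {col!r}", column=col)
    bad = pd.Series(False, index=df.index)
    for phase in ("1", "2"):
        conf = pd.to_numeric(df[f"conf{phase}"], errors="coerce")
        u = pd.to_numeric(df[f"u{phase}"], errors="coerce")
        rt = pd.to_numeric(df[f"rt{phase}"], errors="coerce")
        bad |= ~conf.isin([1, 2, 3, 4])
        bad |= (u != 5 - conf)
        bad |= ~((rt > 0) & (rt <= 2.0))
    bad |= pd.to_numeric(df["delta_u"], errors="coerce") != (
        pd.to_numeric(df["u1"], errors="coerce") - pd.to_numeric(df["u2"], errors="coerce")
    )
    n_bad = int(bad.sum())
    if n_bad and not drop_invalid:
        first = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableValidationError(
            f"{n_bad} invalid rows (first at line {first + 2})", n_rejected=n_bad
        )
    out = df[~bad].reset_index(drop=True)
    for col in _INT_COLS:
        out[col] = out[col].astype(int)
    out.attrs["n_rejected"] = n_bad
    return out


def export_schedule_ev3(schedule: EventSchedule, out_dir) -> None:
    """Write one 3-column (onset, duration, weight) text file per regressor."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ev = schedule.events
    specs = {
        "decision": ("onset_decision", "dur_decision"),
        "post_decision": ("onset_post", "dur_post"),
        "iti": ("onset_iti", "dur_iti"),
    }
    for name, (on, dur) in specs.items():
        sub = ev if name == "iti" else ev[ev["condition"] == "task"]
        arr = np.column_stack([sub[on], sub[dur], np.ones(len(sub))])
        np.savetxt(out_dir / f"{name}.txt", arr, fmt="%.4f", delimiter="\t")


def write_connectivity(matrices: dict[str, pd.DataFrame], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cond, mat in matrices.items():
        mat.to_csv(out_dir / f"connectivity_{cond}.csv")
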