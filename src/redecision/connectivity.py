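"""PPI and trial-wise (beta-series) connectivity on ROI time series.

The psycho-physiological interaction (PPI) takes a seed region's series with
the mean and the uncertainty-modulated component removed as the
physiological factor, the HRF-convolved uncertainty regressor over the
redecision phase as the psychological factor, and their elementwise product
as the interaction term.  Beta-series connectivity removes the mean and the
modulated regressors (plus their interactions) from each ROI, refits one
HRF-convolved redecision regressor per trial segment, and correlates the
per-trial regression values between ROI pairs within a condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glm import (
    DesignMatrix,
    EventSchedule,
    MICROTIME_DT,
    _boxcar,
    build_design,
    canonical_hrf,
)

__all__ = [
    "PPIResult",
    "ppi_design",
    "ppi_fit",
    "trialwise_connectivity",
    "epoch_timecourses",
    "InsufficientTrialsError",
]


class InsufficientTrialsError(ValueError):
    """A condition has too few trials for a correlation."""


@dataclass
class PPIResult:
    physiological: np.ndarray
    psychological: np.ndarray
    interaction: np.ndarray
    design: DesignMatrix


def _convolved_modulated_regressor(
    schedule: EventSchedule,
    tr: float,
    n_volumes: int,
    values: np.ndarray,
    condition: str = "task",
    demean: bool = True,
    dt: float = MICROTIME_DT,
) -> np.ndarray:
    """HRF-convolved redecision-phase boxcar weighted by per-trial values."""
    ev = schedule.condition(condition)
    run_len = max(schedule.run_duration, n_volumes * tr)
    tgrid = np.arange(0, run_len + dt, dt)
    w = np.asarray(values, dtype=float)
    if demean:
        w = w - w.mean()
    x = _boxcar(tgrid, ev["onset_post"], ev["dur_post"], w)
    h = canonical_hrf(dt)
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return np.convolve(x, h)[: len(tgrid)][vol_idx]


def ppi_design(
    physio: np.ndarray,
    u1: Sequence[float],
    schedule: EventSchedule,
    tr: float,
) -> PPIResult:
    """Construct the PPI regressors from a seed series and trial uncertainties.

    The physiological factor is the seed series with its mean and the
    component correlated with the (HRF-convolved, demeaned) uncertainty
    regressor removed; the psychological factor is that uncertainty
    regressor; the interaction is their elementwise product.  Adding a
    constant to the seed series leaves the interaction unchanged.
    """
    physio = np.asarray(physio, dtype=float)
    n_vol = physio.shape[0]
    ev = schedule.condition("task")
    u1 = np.asarray(u1, dtype=float)
    if u1.shape != (len(ev),):
        raise ValueError("u1 must have one value per task trial")
    psych = _convolved_modulated_regressor(schedule, tr, n_vol, u1)
    X = np.column_stack([np.ones(n_vol), psych])
    beta, *_ = np.linalg.lstsq(X, physio, rcond=None)
    phys = physio - X @ beta
    interaction = phys * psych
    design = DesignMatrix(
        values=np.column_stack([phys, psych, interaction]),
        tr=tr,
        labels=["physiological", "psychological", "ppi_interaction"],
    )
    return PPIResult(physiological=phys, psychological=psych,
                     interaction=interaction, design=design)


def ppi_fit(target: np.ndarray, ppi: PPIResult) -> pd.Series:
    """OLS of a target ROI on [1, physiological, psychological, interaction].

    Returns the coefficient series; the coupling strength is
    ``result['ppi_interaction']``.
    """
    from .glm import fit_glm

    fit = fit_glm(np.asarray(target, dtype=float), ppi.design)
    return fit.beta


def _trial_betas(
    resid: np.ndarray,
    schedule: EventSchedule,
    tr: float,
    dt: float = MICROTIME_DT,
) -> pd.DataFrame:
    """One redecision-phase regression value per trial from residual series."""
    n_vol = resid.shape[0]
    run_len = max(schedule.run_duration, n_vol * tr)
    tgrid = np.arange(0, run_len + dt, dt)
    h = canonical_hrf(dt)
    vol_idx = np.round(np.arange(n_vol) * tr / dt).astype(int)
    vol_times = np.arange(n_vol) * tr
    ev = schedule.events
    trial_len = schedule.timing.trial_span + schedule.timing.iti
    rows = []
    for _, trial in ev.iterrows():
        start = trial["onset_decision"] - schedule.timing.cue
        seg = (vol_times >= start) & (vol_times < start + trial_len + 10.0)
        x = np.convolve(_boxcar(tgrid, [trial["onset_post"]], [trial["dur_post"]]), h)
        x = x[: len(tgrid)][vol_idx][seg]
        y = resid[seg]
        x = x - x.mean()
        y = y - y.mean()
        denom = x @ x
        beta = float(x @ y / denom) if denom > 0 else np.nan
        rows.append({"trial": int(trial["trial"]), "condition": trial["condition"],
                     "beta": beta})
    return pd.DataFrame(rows)


def trialwise_connectivity(
    roi_series: Mapping[str, np.ndarray],
    schedule: EventSchedule,
    tr: float,
    conditions: Sequence[str] = ("task", "control"),
    min_trials: int = 3,
) -> dict[str, pd.DataFrame]:
    """Beta-series ROI-pair correlation matrices, one per condition.

    Per ROI: regress out the mean, the three event regressors, the
    u1/RT/uncertainty-reduction modulated regressors and their pairwise
    interactions; extract one redecision-phase regression value per trial
    from the residuals; correlate those values across trials for each ROI
    pair within each condition.  Matrices are symmetric with unit diagonal.
    """
    names = list(roi_series)
    if len(names) < 2:
        raise ValueError("need at least 2 ROIs")
    n_vol = len(next(iter(roi_series.values())))
    ev = schedule.events

    # nuisance design: events + modulators + pairwise modulator interactions
    sched_ext = EventSchedule(events=ev.copy(), timing=schedule.timing)
    for a, b in (("u1", "rt"), ("u1", "delta_u"), ("rt", "delta_u")):
        sched_ext.events[f"{a}_x_{b}"] = sched_ext.events[a] * sched_ext.events[b]
    nuisance = build_design(
        sched_ext, tr, n_volumes=n_vol,
        modulators=("u1", "rt", "delta_u", "u1_x_rt", "u1_x_delta_u", "rt_x_delta_u"),
        orthogonalize=False,
    )
    Xn = np.column_stack([np.ones(n_vol), nuisance.values])

    betas: dict[str, pd.DataFrame] = {}
    for name in names:
        y = np.asarray(roi_series[name], dtype=float)
        if y.shape != (n_vol,):
            raise ValueError("all ROI series must share one length")
        b, *_ = np.linalg.lstsq(Xn, y, rcond=None)
        betas[name] = _trial_betas(y - Xn @ b, schedule, tr)

    out: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        mask = betas[names[0]]["condition"] == cond
        if int(mask.sum()) < min_trials:
            raise InsufficientTrialsError(
                f"condition {cond!r} has {int(mask.sum())} trials (< {min_trials})"
            )
        series = {n: betas[n].loc[mask, "beta"].to_numpy() for n in names}
        mat = np.eye(len(names))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = np.corrcoef(series[names[i]], series[names[j]])[0, 1]
                mat[i, j] = mat[j, i] = r
        out[cond] = pd.DataFrame(mat, index=names, columns=names)
    return out


def epoch_timecourses(
    roi_series: np.ndarray | Sequence[np.ndarray],
    onsets: Sequence[float],
    window: float,
    tr: float,
    upsample: int = 10,
) -> dict:
    """Event-locked mean epochs with linear-interpolation oversampling.

    ``roi_series`` may be one series (one participant) or a sequence of
    series.  Each series is oversampled ``upsample``-fold by linear
    interpolation, epochs of ``window`` seconds are extracted from each
    onset, and averages are taken across trials and then across
    participants; the SEM is computed between participants.  Epochs that
    would run past the end of a series are truncated and flagged.
    """
    if isinstance(roi_series, np.ndarray) and roi_series.ndim == 1:
        roi_series = [roi_series]
    dt = tr / upsample
    n_samp = int(round(window / dt))
    epoch_t = np.arange(n_samp) * dt
    per_participant = []
    truncated = False
    for series in roi_series:
        series = np.asarray(series, dtype=float)
        t_orig = np.arange(series.shape[0]) * tr
        t_up = np.arange(0, t_orig[-1] + dt / 2, dt)
        up = np.interp(t_up, t_orig, series)
        epochs = []
        for onset in onsets:
            i0 = int(round(onset / dt))
            seg = up[i0 : i0 + n_samp]
            if seg.shape[0] < n_samp:
                truncated = True
                seg = np.concatenate([seg, np.full(n_samp - seg.shape[0], np.nan)])
            epochs.append(seg)
        stack_trials = np.array(epochs)
        # all-NaN tails can occur for fully truncated windows
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_participant.append(np.nanmean(stack_trials, axis=0))
    stack = np.array(per_participant)
    mean = stack.mean(axis=0)
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
           if stack.shape[0] > 1 else np.zeros_like(mean))
    return {"time": epoch_t, "mean": mean, "sem": sem,
            "per_participant": stack, "truncated": truncated}
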