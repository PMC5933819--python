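"""First-level fMRI design machinery for the decision-redecision paradigm.

Each 15-s trial is modelled with three regressors: the initial decision
(onset at stimulus presentation, 2 s plus the differential choice RT), the
post-decision/redecision process (onset at the first confidence judgment,
confidence-report time + re-presentation time + differential RT), and the
inter-trial interval.  Trial-varying covariates (initial uncertainty, RT,
uncertainty reduction) enter as demeaned parametric modulators of the
post-decision regressor and are serially orthogonalized, which is
equivalent to stepwise regression for the last-entered covariate.  Boxcars
are built on a 0.1-s microtime grid, convolved with a canonical
double-gamma HRF, and sampled at volume acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "TimingConfig",
    "EventSchedule",
    "DesignMatrix",
    "GLMFit",
    "ScheduleError",
    "SingularDesignError",
    "build_schedule",
    "canonical_hrf",
    "build_design",
    "vif",
    "simulate_bold",
    "fit_glm",
]

MICROTIME_DT = 0.1  # s; matches the 10x oversampling of the volume TR


class ScheduleError(ValueError):
    """Event timing is inconsistent (e.g. negative duration)."""


class SingularDesignError(np.linalg.LinAlgError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class TimingConfig:
    """Within-trial segment durations (s); defaults reproduce the main design."""

    cue: float = 1.0
    stimulus: float = 2.0
    choice: float = 2.0
    confidence: float = 2.0
    redecision: float = 4.0  # re-presentation (2.0 in the short-redecision variant)
    choice2: float = 2.0
    confidence2: float = 2.0
    iti: float = 2.0

    @property
    def trial_span(self) -> float:
        """Cue onset to end of the second confidence report (15 s nominally)."""
        return (self.cue + self.stimulus + self.choice + self.confidence
                + self.redecision + self.choice2 + self.confidence2)

    def __post_init__(self) -> None:
        for name in ("cue", "stimulus", "choice", "confidence",
                     "redecision", "choice2", "confidence2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"duration {name!r} must be > 0")
        if self.iti < 0:
            raise ValueError("iti must be >= 0")


@dataclass
class EventSchedule:
    """Per-trial event onsets/durations (s) and modulator values."""

    events: pd.DataFrame  # one row per trial
    timing: TimingConfig

    @property
    def run_duration(self) -> float:
        last = self.events.iloc[-1]
        return float(last["onset_iti"] + last["dur_iti"])

    def condition(self, label: str) -> pd.DataFrame:
        return self.events[self.events["condition"] == label]


def build_schedule(
    session: pd.DataFrame,
    timing: TimingConfig = TimingConfig(),
    confidence_report_rt: Optional[Sequence[float]] = None,
) -> EventSchedule:
    """Construct the three-regressor event schedule for one run/session.

    ``session`` is a trial table slice (ordered trials of one run) carrying
    ``rt1``, ``rt2``, ``condition``, ``u1``, ``delta_u``.  Differential RTs
    are each trial's RT minus the mean RT of the control trials (0 when the
    run has no control trials).  The nominal duration of the post-decision
    regressor uses the recorded confidence-report time when supplied,
    otherwise the full confidence window.
    """
    t = timing
    n = len(session)
    if n == 0:
        raise ScheduleError("session has no trials")
    rt1 = session["rt1"].to_numpy(dtype=float)
    rt2 = session["rt2"].to_numpy(dtype=float)
    is_ctrl = (session["condition"] == "control").to_numpy()
    ctrl_rt1 = rt1[is_ctrl].mean() if is_ctrl.any() else 0.0
    ctrl_rt2 = rt2[is_ctrl].mean() if is_ctrl.any() else 0.0
    drt1 = rt1 - ctrl_rt1 if is_ctrl.any() else np.zeros(n)
    drt2 = rt2 - ctrl_rt2 if is_ctrl.any() else np.zeros(n)
    conf_rt = (np.asarray(confidence_report_rt, dtype=float)
               if confidence_report_rt is not None else np.full(n, t.confidence))
    if conf_rt.shape != (n,):
        raise ScheduleError("confidence_report_rt length must match trial count")

    starts = np.arange(n) * (t.trial_span + t.iti)
    onset_dec = starts + t.cue
    dur_dec = t.stimulus + drt1
    onset_post = starts + t.cue + t.stimulus + t.choice
    dur_post = conf_rt + t.redecision + drt2
    onset_iti = starts + t.trial_span
    dur_iti = np.full(n, t.iti)
    if (dur_dec <= 0).any() or (dur_post <= 0).any():
        raise ScheduleError("computed a non-positive event duration")
    if ((onset_dec + dur_dec) > onset_post).any():
        raise ScheduleError("decision event overlaps the post-decision event")

    events = pd.DataFrame({
        "trial": np.arange(n),
        "condition": session["condition"].to_numpy(),
        "onset_decision": onset_dec,
        "dur_decision": dur_dec,
        "onset_post": onset_post,
        "dur_post": dur_post,
        "onset_iti": onset_iti,
        "dur_iti": dur_iti,
        "u1": session["u1"].to_numpy(dtype=float),
        "rt": rt1,
        "delta_u": session["delta_u"].to_numpy(dtype=float),
    })
    return EventSchedule(events=events, timing=t)


def canonical_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, unit peak amplitude.

    Positive gamma peaking near 5 s minus an undershoot gamma (peak:undershoot
    amplitude ratio 6:1), 32-s support.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must be in (0, 1]")
    t = np.arange(0, length + dt, dt)
    h = (_gamma_dist.pdf(t, peak_delay / peak_disp, scale=peak_disp)
         - _gamma_dist.pdf(t, undershoot_delay / undershoot_disp,
                           scale=undershoot_disp) / ratio)
    return h / h.max()


@dataclass
class DesignMatrix:
    values: np.ndarray  # volumes x regressors
    tr: float
    labels: list[str]
    orth_order: tuple[str, ...] = ()

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)


def _boxcar(tgrid: np.ndarray, onsets, durations, weights=None) -> np.ndarray:
    x = np.zeros_like(tgrid)
    w = np.ones(len(onsets)) if weights is None else np.asarray(weights, dtype=float)
    for o, d, wi in zip(onsets, durations, w):
        x[(tgrid >= o) & (tgrid < o + d)] = wi
    return x


def build_design(
    schedule: EventSchedule,
    tr: float,
    n_volumes: Optional[int] = None,
    modulators: Sequence[str] = ("u1", "rt", "delta_u"),
    orthogonalize: bool = True,
    conditions: Sequence[str] = ("task",),
    include_control_regressors: bool = True,
    hrf_kwargs: Optional[dict] = None,
    dt: float = MICROTIME_DT,
) -> DesignMatrix:
    """Build the convolved, optionally serially-orthogonalized design matrix.

    Base columns: decision, post-decision, and ITI regressors for the trials
    in ``conditions`` (plus, when present and requested, a decision and
    post-decision regressor for control trials).  Each modulator multiplies
    the post-decision boxcar after demeaning across the modelled trials, is
    convolved, and is then serially orthogonalized in the listed order: each
    modulated column is residualized against the base columns and all
    earlier modulated columns, which reproduces stepwise regression
    coefficient-for-coefficient.
    """
    ev = schedule.events
    if n_volumes is None:
        n_volumes = int(np.ceil(schedule.run_duration / tr))
    run_len = max(schedule.run_duration, n_volumes * tr)
    tgrid = np.arange(0, run_len + dt, dt)
    h = canonical_hrf(dt, **(hrf_kwargs or {}))
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)

    def conv(x: np.ndarray) -> np.ndarray:
        return np.convolve(x, h)[: len(tgrid)][vol_idx]

    sel = ev["condition"].isin(conditions)
    task_ev = ev[sel]
    if task_ev.empty:
        raise ScheduleError(f"no events for conditions {tuple(conditions)}")

    cols: list[np.ndarray] = []
    labels: list[str] = []

    cols.append(conv(_boxcar(tgrid, task_ev["onset_decision"], task_ev["dur_decision"])))
    labels.append("decision")
    cols.append(conv(_boxcar(tgrid, task_ev["onset_post"], task_ev["dur_post"])))
    labels.append("post_decision")
    cols.append(conv(_boxcar(tgrid, ev["onset_iti"], ev["dur_iti"])))
    labels.append("iti")

    ctrl_ev = ev[~sel]
    if include_control_regressors and not ctrl_ev.empty:
        cols.append(conv(_boxcar(tgrid, ctrl_ev["onset_decision"], ctrl_ev["dur_decision"])))
        labels.append("control_decision")
        cols.append(conv(_boxcar(tgrid, ctrl_ev["onset_post"], ctrl_ev["dur_post"])))
        labels.append("control_post")

    n_base = len(cols)
    for name in modulators:
        if name not in task_ev.columns:
            raise ScheduleError(f"unknown modulator {name!r}")
        m = task_ev[name].to_numpy(dtype=float)
        if m.shape != (len(task_ev),):
            raise ScheduleError(f"modulator {name!r} length must equal trial count")
        m = m - m.mean()  # demeaned before multiplication with the boxcar
        cols.append(conv(_boxcar(tgrid, task_ev["onset_post"], task_ev["dur_post"], m)))
        labels.append(f"post_x_{name}")

    X = np.column_stack(cols)
    if orthogonalize and modulators:
        # serial Gram-Schmidt: each modulated column against base columns,
        # the intercept, and all earlier modulated columns
        ones = np.ones((X.shape[0], 1))
        for j in range(n_base, X.shape[1]):
            prev = np.column_stack([ones, X[:, :j]])
            beta, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
            X[:, j] = X[:, j] - prev @ beta
    return DesignMatrix(values=X, tr=tr, labels=labels,
                        orth_order=tuple(modulators) if orthogonalize else ())


def vif(design: DesignMatrix | np.ndarray, columns: Optional[Sequence[str]] = None):
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    ``R^2_j`` comes from OLS of column j on the other selected columns plus
    an intercept.  Perfectly collinear columns yield ``inf`` (flagged, not
    raised).
    """
    if isinstance(design, DesignMatrix):
        labels = list(design.labels) if columns is None else list(columns)
        X = np.column_stack([design.column(l) for l in labels])
    else:
        X = np.asarray(design, dtype=float)
        labels = [f"col{i}" for i in range(X.shape[1])] if columns is None else list(columns)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 columns")
    if (np.ptp(X, axis=0) == 0).any():
        raise ValueError("VIF requires non-constant columns")
    out = {}
    for j, lab in enumerate(labels):
        y = X[:, j]
        others = np.column_stack(
            [np.ones(X.shape[0])] + [X[:, i] for i in range(X.shape[1]) if i != j]
        )
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot
        out[lab] = float(np.inf) if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def simulate_bold(
    design: DesignMatrix,
    betas: Sequence[float],
    sigma: float,
    rho: float = 0.0,
    rng: np.random.Generator | int = 0,
    intercept: float = 0.0,
) -> np.ndarray:
    """Synthetic ROI BOLD: Y = X beta + AR(1) noise (innovation sd sigma)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (design.values.shape[1],):
        raise ValueError("betas must match the number of design columns")
    n = design.n_volumes
    noise = np.zeros(n)
    if sigma > 0:
        innov = rng.normal(0.0, sigma, size=n)
        noise[0] = innov[0] / np.sqrt(max(1.0 - rho**2, np.finfo(float).tiny)) if abs(rho) < 1 else innov[0]
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + innov[i]
    return intercept + design.values @ betas + noise


@dataclass
class GLMFit:
    beta: pd.Series
    se: pd.Series
    tvalues: pd.Series
    residuals: np.ndarray
    r_squared: float
    vif: dict
    dof: int
    ar1_rho: float = 0.0  # estimated lag-1 residual autocorrelation (prewhitened fits)


def fit_glm(
    y: np.ndarray,
    design: DesignMatrix,
    add_intercept: bool = True,
    prewhiten: bool = False,
) -> GLMFit:
    """Least-squares fit of one ROI series on the design matrix.

    The default is plain OLS, matching a first-level model with no noise
    whitening.  With ``prewhiten=True`` the lag-1 residual autocorrelation
    is estimated from the OLS residuals and one Cochrane-Orcutt step is
    applied (y and X quasi-differenced, then refit), which restores
    near-nominal standard errors under AR(1) noise; plain-OLS intervals
    undercover by a few percentage points when the noise is autocorrelated.
    """
    y = np.asarray(y, dtype=float)
    X = design.values
    labels = list(design.labels)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        labels = ["intercept"] + labels
    if y.shape[0] != X.shape[0]:
        raise ValueError("series length must equal the number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rho_hat = 0.0
    if prewhiten:
        denom = resid[:-1] @ resid[:-1]
        rho_hat = float(resid[1:] @ resid[:-1] / denom) if denom > 0 else 0.0
        y_fit = y[1:] - rho_hat * y[:-1]
        X_fit = X[1:] - rho_hat * X[:-1]
        beta, _, _, _ = np.linalg.lstsq(X_fit, y_fit, rcond=None)
        resid_fit = y_fit - X_fit @ beta
        resid = y - X @ beta  # report residuals on the original scale
    else:
        y_fit, X_fit, resid_fit = y, X, resid
    dof = len(y_fit) - X_fit.shape[1]
    sigma2 = resid_fit @ resid_fit / dof
    cov = sigma2 * np.linalg.inv(X_fit.T @ X_fit)
    se = np.sqrt(np.diag(cov))
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    try:
        vifs = vif(design)
    except ValueError:
        vifs = {}
    return GLMFit(
        beta=pd.Series(beta, index=labels),
        se=pd.Series(se, index=labels),
        tvalues=pd.Series(tvals, index=labels),
        residuals=resid,
        r_squared=float(r2),
        vif=vifs,
        dof=dof,
        ar1_rho=rho_hat,
    )
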