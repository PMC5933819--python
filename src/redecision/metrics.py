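"""Behavioural metacognition statistics.

Implements the nonparametric type-2 ROC (uncertainty sensitivity, A_ROC),
RT-uncertainty correlation, uncertainty bias (mean uncertainty with the
A_ROC component regressed out), accuracy change by redecision, the
Goodman-Kruskal gamma ordinal association, Cronbach's alpha reliability,
Fisher z comparisons of correlations, and cohort-level summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "UndefinedMetricError",
    "type2_roc",
    "rt_uncertainty_correlation",
    "uncertainty_bias",
    "accuracy_change",
    "goodman_kruskal_gamma",
    "cronbach_alpha",
    "fisher_z_compare",
    "summarize_cohort",
    "CohortSummary",
]

_U_LEVELS = (1, 2, 3, 4)


class UndefinedMetricError(ValueError):
    """The statistic is undefined for this input (e.g. no variance)."""


@dataclass(frozen=True)
class ROCCurve:
    """Type-2 ROC points (false-alarm rate, hit rate) and trapezoidal area."""

    points: tuple[tuple[float, float], ...]
    a_roc: float


def type2_roc(u, correct, framing: str = "uncertainty") -> ROCCurve:
    """Nonparametric type-2 ROC from uncertainty ratings and correctness.

    For each threshold ``k`` in 1..4, hit rate = P(u >= k | error) and
    false-alarm rate = P(u >= k | correct): an "uncertain" report flags a
    likely error.  The curve is anchored at (0,0) and (1,1) and the area
    (``a_roc``) is the trapezoidal integral; 0.5 means confidence carries no
    information about accuracy, 1.0 perfect error detection.

    ``framing="confidence"`` sweeps confidence thresholds instead; the two
    framings give the same area.
    """
    u = np.asarray(u, dtype=int)
    correct = np.asarray(correct, dtype=bool)
    if u.shape != correct.shape or u.ndim != 1:
        raise ValueError("u and correct must be 1-D arrays of equal length")
    if not np.isin(u, _U_LEVELS).all():
        raise ValueError("uncertainty levels must be in {1,2,3,4}")
    n_err = int((~correct).sum())
    n_cor = int(correct.sum())
    if n_err == 0 or n_cor == 0:
        raise UndefinedMetricError(
            "type-2 ROC is undefined without both correct and error trials"
        )
    if framing == "confidence":
        # detect correct decisions by high confidence: same area by symmetry
        score, signal = 5 - u, correct
    elif framing == "uncertainty":
        score, signal = u, ~correct
    else:
        raise ValueError("framing must be 'uncertainty' or 'confidence'")

    pts = [(0.0, 0.0)]
    for k in (4, 3, 2, 1):
        fa = float((score[~signal] >= k).mean())
        hit = float((score[signal] >= k).mean())
        pts.append((fa, hit))
    pts.append((1.0, 1.0))
    xs, ys = zip(*pts)
    area = float(np.trapezoid(ys, xs))
    return ROCCurve(points=tuple(pts), a_roc=area)


def rt_uncertainty_correlation(rt, u, alternative: str = "greater"):
    """Pearson correlation of choice RT with decision uncertainty.

    Returns ``(r, t, p)`` with ``t = r * sqrt(n-2) / sqrt(1-r^2)``; the
    default alternative is one-tailed positive (slower when more uncertain).
    """
    rt = np.asarray(rt, dtype=float)
    u = np.asarray(u, dtype=float)
    if rt.size < 3:
        raise UndefinedMetricError("need at least 3 trials")
    if np.ptp(rt) == 0 or np.ptp(u) == 0:
        raise UndefinedMetricError("correlation undefined with zero variance")
    res = stats.pearsonr(rt, u, alternative=alternative)
    r = float(res.statistic)
    n = rt.size
    t = r * math.sqrt(n - 2) / math.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    return r, t, float(res.pvalue)


def uncertainty_bias(mean_u, a_roc) -> tuple[np.ndarray, bool]:
    """Per-participant uncertainty bias: mean uncertainty with A_ROC regressed out.

    OLS of mean uncertainty on A_ROC across participants; the bias is the
    residual plus the grand mean (so biases sum to n times the grand mean).
    If A_ROC has no variance the regression is skipped and the bias falls
    back to the raw mean uncertainty, with ``degenerate=True`` flagged.

    Returns ``(bias, degenerate)``.
    """
    mean_u = np.asarray(mean_u, dtype=float)
    a_roc = np.asarray(a_roc, dtype=float)
    if mean_u.size < 3:
        raise UndefinedMetricError("need at least 3 participants")
    grand = mean_u.mean()
    if np.ptp(a_roc) == 0:
        warnings.warn("A_ROC constant across participants; bias = mean uncertainty")
        return mean_u.copy(), True
    X = np.column_stack([np.ones_like(a_roc), a_roc])
    beta, *_ = np.linalg.lstsq(X, mean_u, rcond=None)
    resid = mean_u - X @ beta
    return resid + grand, False


def accuracy_change(correct1, correct2) -> float:
    """Mean final-decision accuracy minus mean initial-decision accuracy."""
    correct1 = np.asarray(correct1, dtype=float)
    correct2 = np.asarray(correct2, dtype=float)
    if correct1.size == 0:
        raise UndefinedMetricError("need at least one trial")
    return float(correct2.mean() - correct1.mean())


def goodman_kruskal_gamma(x, y) -> float:
    """Goodman-Kruskal gamma: (C - D) / (C + D), ties excluded.

    Counted from the contingency table of the two ordinal variables, which
    is O(K^2) in the number of distinct levels rather than O(n^2) in trials.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=float)
    np.add.at(table, (xi, yi), 1.0)
    C = D = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij == 0:
                continue
            C += nij * table[i + 1 :, j + 1 :].sum()
            D += nij * table[i + 1 :, :j].sum()
    if C + D == 0:
        raise UndefinedMetricError("gamma undefined: all pairs are tied")
    return float((C - D) / (C + D))


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha of a participants x sessions matrix (no missing cells)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 participants and >= 2 sessions")
    if np.isnan(m).any():
        raise UndefinedMetricError("missing cells are not allowed (no imputation)")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedMetricError("alpha undefined: total score has no variance")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def fisher_z_compare(r, n, r2=None, n2=None, alternative: str = "two-sided"):
    """Fisher z test of one correlation against 0, or of two correlations.

    Single sample: ``z = atanh(r) * sqrt(n - 3)``.  Two samples:
    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``.
    Returns ``(z, p)``.
    """
    for rr in (r, r2):
        if rr is not None and abs(rr) >= 1:
            raise UndefinedMetricError("|r| = 1: Fisher transform is infinite")
    if n < 4 or (n2 is not None and n2 < 4):
        raise ValueError("need n >= 4")
    if r2 is None:
        z = math.atanh(r) * math.sqrt(n - 3)
    else:
        z = (math.atanh(r) - math.atanh(r2)) / math.sqrt(1 / (n - 3) + 1 / (n2 - 3))
    if alternative == "two-sided":
        p = 2 * stats.norm.sf(abs(z))
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return float(z), float(p)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

_METRIC_COLS = [
    "participant",
    "session",
    "task",
    "n_trials",
    "a_roc1",
    "a_roc2",
    "r_rt_uncertainty",
    "mean_uncertainty",
    "uncertainty_bias",
    "accuracy1",
    "accuracy2",
    "accuracy_change",
    "gamma_u1_reduction",
]

_REQUIRED_COLUMNS = [
    "participant", "task", "session", "condition",
    "correct1", "conf1", "u1", "rt1", "correct2", "conf2", "u2", "delta_u",
]


@dataclass
class CohortSummary:
    """Per-session metrics, reliability report, and Fig-2-style tables."""

    per_session: pd.DataFrame
    per_participant: pd.DataFrame
    reliability: dict = field(default_factory=dict)
    error_rate_by_u: pd.DataFrame | None = None
    reduction_by_u1: pd.DataFrame | None = None


def _session_metrics(df: pd.DataFrame) -> dict:
    u1 = df["u1"].to_numpy()
    c1 = df["correct1"].to_numpy(dtype=bool)
    u2 = df["u2"].to_numpy()
    c2 = df["correct2"].to_numpy(dtype=bool)
    out = {"n_trials": len(df)}
    try:
        out["a_roc1"] = type2_roc(u1, c1).a_roc
    except UndefinedMetricError:
        out["a_roc1"] = np.nan
    try:
        out["a_roc2"] = type2_roc(u2, c2).a_roc
    except UndefinedMetricError:
        out["a_roc2"] = np.nan
    try:
        out["r_rt_uncertainty"] = rt_uncertainty_correlation(df["rt1"], u1)[0]
    except UndefinedMetricError:
        out["r_rt_uncertainty"] = np.nan
    out["mean_uncertainty"] = float(u1.mean())
    out["accuracy1"] = float(c1.mean())
    out["accuracy2"] = float(c2.mean())
    out["accuracy_change"] = out["accuracy2"] - out["accuracy1"]
    try:
        out["gamma_u1_reduction"] = goodman_kruskal_gamma(u1, df["delta_u"])
    except UndefinedMetricError:
        out["gamma_u1_reduction"] = np.nan
    return out


def summarize_cohort(cohort: pd.DataFrame) -> CohortSummary:
    """Aggregate a tidy cohort trial table into the behavioural summaries.

    Control trials are excluded from all metacognition metrics.  Uncertainty
    bias is estimated across participants within each session x task (OLS of
    mean uncertainty on A_ROC) and then averaged per participant.  Reliability
    (Cronbach's alpha) of A_ROC, accuracy change, and uncertainty bias is
    reported across sessions within each task and across the two tasks
    (session-averaged); it is empty for single-session input.
    """
    for col in _REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    task_df = cohort[cohort["condition"] == "task"]
    if task_df.empty:
        raise ValueError("cohort table contains no task trials")

    rows = []
    for (participant, session, task), grp in task_df.groupby(
        ["participant", "session", "task"], sort=True
    ):
        rec = {"participant": participant, "session": session, "task": task}
        rec.update(_session_metrics(grp))
        rows.append(rec)
    per_session = pd.DataFrame(rows)

    # uncertainty bias: across participants within session x task
    per_session["uncertainty_bias"] = np.nan
    for (session, task), grp in per_session.groupby(["session", "task"]):
        ok = grp["a_roc1"].notna()
        if ok.sum() >= 3:
            bias, _ = uncertainty_bias(
                grp.loc[ok, "mean_uncertainty"], grp.loc[ok, "a_roc1"]
            )
            per_session.loc[grp.index[ok], "uncertainty_bias"] = bias
    per_session = per_session[_METRIC_COLS]

    per_participant = (
        per_session.drop(columns=["session"])
        .groupby(["participant", "task"], sort=True)
        .mean()
        .reset_index()
    )

    reliability: dict = {}
    n_sessions = per_session["session"].nunique()
    tasks = sorted(per_session["task"].unique())
    metrics = ["a_roc1", "accuracy_change", "uncertainty_bias"]
    if n_sessions >= 2:
        for task in tasks:
            sub = per_session[per_session["task"] == task]
            for metric in metrics:
                mat = sub.pivot(index="participant", columns="session", values=metric)
                if mat.notna().all().all() and mat.shape[0] >= 2:
                    reliability[f"alpha_{metric}_{task}"] = cronbach_alpha(mat.to_numpy())
    if len(tasks) == 2:
        for metric in metrics:
            mat = per_participant.pivot(index="participant", columns="task", values=metric)
            if mat.notna().all().all() and mat.shape[0] >= 2:
                reliability[f"alpha_{metric}_cross_task"] = cronbach_alpha(mat.to_numpy())

    # Fig-2-style tables: error rate per uncertainty level, and uncertainty
    # reduction / final uncertainty as a function of initial uncertainty
    err_rows = []
    for k in _U_LEVELS:
        row = {"u_level": k}
        sel1 = task_df["u1"] == k
        sel2 = task_df["u2"] == k
        row["error_rate_initial"] = float(1 - task_df.loc[sel1, "correct1"].mean()) if sel1.any() else np.nan
        row["error_rate_final"] = float(1 - task_df.loc[sel2, "correct2"].mean()) if sel2.any() else np.nan
        err_rows.append(row)
    error_rate_by_u = pd.DataFrame(err_rows)

    red = (
        task_df.groupby("u1")[["delta_u", "u2"]]
        .mean()
        .rename(columns={"delta_u": "mean_uncertainty_reduction", "u2": "mean_final_uncertainty"})
        .reset_index()
    )

    return CohortSummary(
        per_session=per_session,
        per_participant=per_participant,
        reliability=reliability,
        error_rate_by_u=error_rate_by_u,
        reduction_by_u1=red,
    )
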