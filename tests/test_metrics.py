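"""Behavioural statistics against independent brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redecision.metrics import (
    UndefinedMetricError,
    accuracy_change,
    cronbach_alpha,
    fisher_z_compare,
    goodman_kruskal_gamma,
    rt_uncertainty_correlation,
    summarize_cohort,
    type2_roc,
    uncertainty_bias,
)

# ---------------------------------------------------------------------------
# independent oracles (coded from the definitions, not from the implementation)
# ---------------------------------------------------------------------------


def rank_auc_oracle(u, correct):
    """P(random error trial has higher u than random correct trial), ties 1/2."""
    u = np.asarray(u)
    correct = np.asarray(correct, dtype=bool)
    err, cor = u[~correct], u[correct]
    total = 0.0
    for e in err:
        for c in cor:
            total += 1.0 if e > c else (0.5 if e == c else 0.0)
    return total / (len(err) * len(cor))


def threshold_sweep_oracle(u, correct):
    """Explicit threshold sweep + trapezoid, built independently."""
    u = np.asarray(u)
    correct = np.asarray(correct, dtype=bool)
    pts = [(0.0, 0.0)]
    for k in (4, 3, 2, 1):
        pts.append(((u[correct] >= k).sum() / correct.sum(),
                    (u[~correct] >= k).sum() / (~correct).sum()))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def gamma_pairs_oracle(x, y):
    """O(n^2) concordant/discordant pair count."""
    x, y = np.asarray(x), np.asarray(y)
    c = d = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return (c - d) / (c + d)


def alpha_covariance_oracle(m):
    """Alpha from the item covariance matrix: k/(k-1) * (1 - tr(C)/sum(C))."""
    C = np.cov(np.asarray(m, dtype=float), rowvar=False)
    k = C.shape[0]
    return k / (k - 1) * (1.0 - np.trace(C) / C.sum())


# fixed mixed-separation fixture: corrects at u=1..4 with counts (10,5,3,2),
# errors with counts (1,2,3,4); area frozen from the sweep oracle
FIXTURE_U = np.concatenate([np.repeat([1, 2, 3, 4], [10, 5, 3, 2]),
                            np.repeat([1, 2, 3, 4], [1, 2, 3, 4])])
FIXTURE_OK = np.concatenate([np.ones(20, bool), np.zeros(10, bool)])
FIXTURE_AROC = 0.7775


class TestType2ROC:
    def test_single_uncertainty_level_is_chance(self):
        roc = type2_roc([2] * 10, [True] * 5 + [False] * 5)
        assert roc.a_roc == pytest.approx(0.5, abs=1e-12)

    def test_perfect_separation(self):
        roc = type2_roc([1, 1, 1, 4, 4], [True, True, True, False, False])
        assert roc.a_roc == pytest.approx(1.0, abs=1e-12)

    def test_fixture_matches_frozen_sweep_value(self):
        roc = type2_roc(FIXTURE_U, FIXTURE_OK)
        assert roc.a_roc == pytest.approx(FIXTURE_AROC, abs=1e-12)
        assert roc.a_roc == pytest.approx(threshold_sweep_oracle(FIXTURE_U, FIXTURE_OK), abs=1e-12)

    def test_curve_points_monotone_and_anchored(self):
        roc = type2_roc(FIXTURE_U, FIXTURE_OK)
        xs, ys = zip(*roc.points)
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)
        assert all(a <= b + 1e-12 for a, b in zip(xs, xs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(ys, ys[1:]))

    @given(st.lists(st.tuples(st.integers(1, 4), st.booleans()), min_size=4, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_equals_rank_auc_oracle(self, trials):
        u = np.array([t[0] for t in trials])
        ok = np.array([t[1] for t in trials])
        if ok.all() or (~ok).all():
            with pytest.raises(UndefinedMetricError):
                type2_roc(u, ok)
            return
        assert type2_roc(u, ok).a_roc == pytest.approx(rank_auc_oracle(u, ok), abs=1e-12)

    def test_monotone_relabeling_invariance(self):
        u = np.array([1, 1, 2, 2, 2, 1, 2, 1])
        ok = np.array([1, 1, 1, 0, 0, 1, 0, 0], bool)
        relabeled = np.where(u == 1, 2, 4)  # strictly monotone map {1,2}->{2,4}
        assert type2_roc(u, ok).a_roc == pytest.approx(type2_roc(relabeled, ok).a_roc, abs=1e-12)

    def test_confidence_framing_same_area(self):
        a = type2_roc(FIXTURE_U, FIXTURE_OK, framing="uncertainty").a_roc
        b = type2_roc(FIXTURE_U, FIXTURE_OK, framing="confidence").a_roc
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(UndefinedMetricError):
            type2_roc([1, 2, 3], [True, True, True])
        with pytest.raises(ValueError):
            type2_roc([0, 2], [True, False])


class TestRTUncertainty:
    def test_exact_linear_gives_unit_correlation(self):
        u = np.array([1, 2, 3, 4, 2, 3])
        r, t, p = rt_uncertainty_correlation(0.5 + 0.3 * u, u)
        assert r == pytest.approx(1.0)

    def test_independent_is_near_zero(self):
        rng = np.random.default_rng(0)
        u = rng.integers(1, 5, 10000)
        rt = rng.uniform(0.2, 2.0, 10000)
        r, _, _ = rt_uncertainty_correlation(rt, u)
        assert abs(r) < 0.05

    def test_t_statistic_formula(self):
        rng = np.random.default_rng(1)
        u = rng.integers(1, 5, 50)
        rt = 0.5 + 0.2 * u + rng.normal(0, 0.3, 50)
        r, t, p = rt_uncertainty_correlation(rt, u)
        assert t == pytest.approx(r * math.sqrt(48) / math.sqrt(1 - r * r))

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedMetricError):
            rt_uncertainty_correlation([1.0, 1.0, 1.0], [1, 2, 3])


class TestUncertaintyBias:
    def test_constant_a_roc_falls_back_to_mean_u(self):
        mean_u = np.array([2.0, 2.5, 3.0])
        with pytest.warns(UserWarning):
            bias, degenerate = uncertainty_bias(mean_u, [0.8, 0.8, 0.8])
        assert degenerate
        assert bias == pytest.approx(mean_u)

    def test_perfect_linear_gives_grand_mean(self):
        a_roc = np.array([0.6, 0.7, 0.8, 0.9])
        mean_u = 1.0 + 2.0 * a_roc
        bias, degenerate = uncertainty_bias(mean_u, a_roc)
        assert not degenerate
        assert bias == pytest.approx(np.full(4, mean_u.mean()))

    def test_biases_sum_to_n_grand_mean(self):
        rng = np.random.default_rng(2)
        a_roc = rng.uniform(0.5, 1.0, 12)
        mean_u = 1 + a_roc + rng.normal(0, 0.2, 12)
        bias, _ = uncertainty_bias(mean_u, a_roc)
        assert bias.sum() == pytest.approx(12 * mean_u.mean())

    def test_planted_offsets_recovered_in_rank_order(self):
        rng = np.random.default_rng(3)
        a_roc = rng.uniform(0.5, 1.0, 10)
        planted = np.linspace(-0.5, 0.5, 10)
        rng.shuffle(planted)
        # make the planted offsets orthogonal to the regressor in-sample so
        # the regression cannot absorb any of them
        X = np.column_stack([np.ones(10), a_roc])
        planted = planted - X @ np.linalg.lstsq(X, planted, rcond=None)[0]
        mean_u = 2.5 - 1.5 * a_roc + planted
        bias, _ = uncertainty_bias(mean_u, a_roc)
        from scipy.stats import spearmanr

        assert spearmanr(bias, planted).statistic == pytest.approx(1.0)


class TestAccuracyChange:
    def test_identical_phases_zero(self):
        c = [1, 0, 1, 1]
        assert accuracy_change(c, c) == 0.0

    def test_arithmetic(self):
        assert accuracy_change([1, 0, 1, 0], [1, 1, 1, 0]) == pytest.approx(0.25)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        c1 = rng.integers(0, 2, 100)
        c2 = rng.integers(0, 2, 100)
        assert accuracy_change(c1, c2) == pytest.approx(-accuracy_change(c2, c1))


class TestGamma:
    def test_strictly_increasing_is_one(self):
        assert goodman_kruskal_gamma([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_strictly_decreasing_is_minus_one(self):
        assert goodman_kruskal_gamma([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_contingency_fixture_matches_pair_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(1, 5, 80)
        y = np.clip(x + rng.integers(-2, 3, 80), 1, 4)
        assert goodman_kruskal_gamma(x, y) == pytest.approx(gamma_pairs_oracle(x, y), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_equals_bruteforce_on_random_ordinals(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        trivial = all(
            np.sign(x[i] - x[j]) * np.sign(y[i] - y[j]) == 0
            for i in range(len(x)) for j in range(i + 1, len(x))
        )
        if trivial:
            with pytest.raises(UndefinedMetricError):
                goodman_kruskal_gamma(x, y)
            return
        assert goodman_kruskal_gamma(x, y) == pytest.approx(gamma_pairs_oracle(x, y), abs=1e-12)

    def test_all_tied_raises(self):
        with pytest.raises(UndefinedMetricError):
            goodman_kruskal_gamma([1, 1, 1], [2, 2, 2])


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([0.7, 0.8, 0.9, 0.6, 0.75])
        m = np.column_stack([col, col, col])
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(4000, 4))
        assert abs(cronbach_alpha(m)) < 0.1

    def test_fixture_matches_covariance_oracle(self):
        m = np.array([
            [0.81, 0.78, 0.85, 0.80, 0.79],
            [0.62, 0.66, 0.60, 0.65, 0.64],
            [0.90, 0.88, 0.93, 0.91, 0.89],
        ])
        assert cronbach_alpha(m) == pytest.approx(alpha_covariance_oracle(m), abs=1e-12)

    def test_missing_cells_raise(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 2.5]])
        with pytest.raises(UndefinedMetricError):
            cronbach_alpha(m)


class TestFisherZ:
    def test_zero_correlation_gives_zero(self):
        z, p = fisher_z_compare(0.0, 20)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_equal_correlations_give_zero(self):
        z, _ = fisher_z_compare(0.45, 30, r2=0.45, n2=50)
        assert z == pytest.approx(0.0)

    def test_study_scale_value_against_reference(self):
        # atanh(0.61) * sqrt(21 - 3), evaluated independently
        z, p = fisher_z_compare(0.61, 21)
        assert z == pytest.approx(0.5 * math.log(1.61 / 0.39) * math.sqrt(18), rel=1e-12)
        assert 0 < p < 0.01

    def test_perfect_correlation_raises(self):
        with pytest.raises(UndefinedMetricError):
            fisher_z_compare(1.0, 10)


class TestSummarizeCohort:
    def test_single_session_has_metrics_but_no_reliability(self, run_table):
        out = summarize_cohort(run_table)
        assert out.reliability == {}
        assert len(out.per_session) == 1
        row = out.per_session.iloc[0]
        assert 0 <= row["a_roc1"] <= 1
        assert row["n_trials"] == 120  # control trials excluded

    def test_error_rate_increases_with_uncertainty(self, small_cohort):
        out = summarize_cohort(small_cohort)
        err = out.error_rate_by_u["error_rate_initial"].to_numpy()
        assert (np.diff(err) > 0).all()

    def test_reduction_table_monotone(self, small_cohort):
        out = summarize_cohort(small_cohort)
        red = out.reduction_by_u1["mean_uncertainty_reduction"].to_numpy()
        assert (np.diff(red) > 0).all()

    def test_reliability_keys_present_for_multisession(self, small_cohort):
        out = summarize_cohort(small_cohort)
        assert "alpha_a_roc1_sudoku" in out.reliability
        assert "alpha_a_roc1_cross_task" in out.reliability

    def test_missing_column_named(self, run_table):
        with pytest.raises(ValueError, match="conf1"):
            summarize_cohort(run_table.drop(columns=["conf1"]))

    def test_per_participant_averages_sessions(self, small_cohort):
        out = summarize_cohort(small_cohort)
        one = out.per_session.query("participant == 0 and task == 'sudoku'")
        avg = out.per_participant.query("participant == 0 and task == 'sudoku'")
        assert avg["a_roc1"].iloc[0] == pytest.approx(one["a_roc1"].mean())
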