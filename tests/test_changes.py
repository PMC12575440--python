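"""Change scores, effect sizes, block contrast and adjusted regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cyclephys.changes import (
    change_scores,
    cohens_d,
    compare_blocks,
    fit_adjusted_regression,
    rhea_label,
)


def _long(records):
    return pd.DataFrame(records, columns=["participant_id", "block", "outcome", "value"])


class TestChangeScores:
    def test_single_participant_pct(self):
        pre = _long([("P1", "MIT", "po_4mmol", 4.0)])
        post = _long([("P1", "MIT", "po_4mmol", 4.2)])
        scores, n_un = change_scores(pre, post)
        assert n_un == 0
        assert scores["delta"].iloc[0] == pytest.approx(0.2)
        assert scores["pct"].iloc[0] == pytest.approx(5.0)

    def test_unmatched_rows_excluded_and_counted(self):
        pre = _long([("P1", "MIT", "x", 4.0), ("P2", "MIT", "x", 5.0)])
        post = _long([("P1", "MIT", "x", 4.2), ("P3", "MIT", "x", 5.0)])
        scores, n_un = change_scores(pre, post)
        assert len(scores) == 1 and n_un == 2

    def test_pre_equals_post_gives_zero_deltas(self):
        pre = _long([("P1", "MIT", "x", 4.0), ("P2", "HIT", "x", 5.0)])
        scores, _ = change_scores(pre, pre.copy())
        assert (scores["delta"] == 0).all()

    def test_percent_point_outcomes_use_delta(self):
        pre = _long([("P1", "MIT", "ge_fresh_3rd", 19.6)])
        post = _long([("P1", "MIT", "ge_fresh_3rd", 19.9)])
        scores, _ = change_scores(pre, post)
        assert scores["pct"].iloc[0] == pytest.approx(0.3)

    @given(
        pre=st.lists(st.floats(min_value=0.5, max_value=10), min_size=1, max_size=10),
        deltas=st.lists(st.floats(min_value=-0.4, max_value=0.4), min_size=10, max_size=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_pct_and_delta_consistent(self, pre, deltas):
        records = [(f"P{i}", "MIT", "x", v) for i, v in enumerate(pre)]
        post = [(f"P{i}", "MIT", "x", v + d) for (i, v), d in
                zip(enumerate(pre), deltas)]
        scores, _ = change_scores(_long(records), _long(post))
        np.testing.assert_allclose(
            scores["pct"] * scores["pre"] / 100.0, scores["delta"], atol=1e-10
        )


class TestCohensD:
    def test_identical_samples(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_pooled_sd(self):
        a, b = [2.0, 4.0, 6.0], [0.0, 2.0, 4.0]  # means 4 and 2, both SD 2
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 3.0, 5.0], [2.0, 2.5, 6.0]
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_undefined(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([2.0, 2.0], [3.0, 3.0])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_equals_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1, 2, size=rng.integers(2, 20))
        b = rng.normal(0, 1, size=rng.integers(2, 20))
        na, nb = len(a), len(b)
        pooled = np.sqrt(
            ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        )
        assert cohens_d(a, b) == pytest.approx((np.mean(a) - np.mean(b)) / pooled)


class TestRheaLabel:
    @pytest.mark.parametrize(
        "d, label",
        [(0.0, "trivial"), (0.24, "trivial"), (0.25, "small"), (-0.34, "small"),
         (0.49, "small"), (0.5, "moderate"), (0.64, "moderate"), (1.0, "moderate"),
         (1.01, "large"), (-2.0, "large")],
    )
    def test_cuts(self, d, label):
        assert rhea_label(d) == label


def _paired_scores(delta_a, delta_b, base_a=None, base_b=None, outcome="x"):
    n = len(delta_a)
    base_a = np.full(n, 4.0) if base_a is None else np.asarray(base_a)
    base_b = np.full(n, 4.0) if base_b is None else np.asarray(base_b)
    rows = []
    for i in range(n):
        rows.append({"participant_id": f"P{i}", "block": "MIT", "outcome": outcome,
                     "pre": base_a[i], "post": base_a[i] + delta_a[i],
                     "delta": delta_a[i], "pct": 100 * delta_a[i] / base_a[i]})
        rows.append({"participant_id": f"P{i}", "block": "HIT", "outcome": outcome,
                     "pre": base_b[i], "post": base_b[i] + delta_b[i],
                     "delta": delta_b[i], "pct": 100 * delta_b[i] / base_b[i]})
    return pd.DataFrame(rows)


class TestCompareBlocks:
    def test_identical_deltas_give_null_contrast(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.2, 0.1, 12)
        scores = _paired_scores(d, d)
        cmp_ = compare_blocks(scores, "x")
        assert cmp_.contrast == pytest.approx(0.0)
        assert cmp_.contrast_p == pytest.approx(1.0)
        assert cmp_.d == pytest.approx(0.0)

    def test_detects_large_block_difference(self):
        rng = np.random.default_rng(2)
        scores = _paired_scores(rng.normal(0.5, 0.05, 15), rng.normal(0.0, 0.05, 15),
                                base_a=rng.normal(4, 0.4, 15), base_b=rng.normal(4, 0.4, 15))
        cmp_ = compare_blocks(scores, "x")
        assert cmp_.contrast == pytest.approx(0.5, abs=0.06)
        assert cmp_.contrast_p < 1e-6
        assert cmp_.d_label == "large"

    def test_incomplete_pairs_excluded(self):
        rng = np.random.default_rng(3)
        scores = _paired_scores(rng.normal(0, 0.1, 10), rng.normal(0, 0.1, 10))
        scores = scores.iloc[:-1]  # drop one rider's HIT row
        cmp_ = compare_blocks(scores, "x")
        assert cmp_.n == 9 and cmp_.n_excluded == 1

    def test_rejection_rate_matches_analytic_paired_t_power(self):
        """True difference 0.10, SD 0.15, n=22: ANCOVA power ~ noncentral-t power."""
        n, reps, true, sd = 22, 500, 0.10, 0.15
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(reps):
            scores = _paired_scores(
                rng.normal(true, sd / np.sqrt(2), n), rng.normal(0.0, sd / np.sqrt(2), n),
                base_a=rng.normal(4, 0.4, n), base_b=rng.normal(4, 0.4, n),
            )
            rejections += compare_blocks(scores, "x").contrast_p <= 0.05
        # independent oracle: power of the paired t-test from the noncentral t
        ncp = true / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit, n - 1, ncp)
        assert rejections / reps == pytest.approx(power, abs=0.05)


class TestAdjustedRegression:
    def test_perfect_linear_fit(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "z": x ** 2, "y": 2.0 * x + 0.5 * x ** 2 + 1.0})
        fit = fit_adjusted_regression(df, "y", "x", covariates=["z"])
        assert fit.estimate == pytest.approx(2.0)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=["y", "x", "c1", "c2"])
        fit = fit_adjusted_regression(df, "y", "x", covariates=["c1", "c2"])
        n, p = 30, 3
        assert fit.r2_adj == pytest.approx(1 - (1 - fit.r2) * (n - 1) / (n - p - 1))
        assert fit.r2_adj <= fit.r2

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 3))
        y = X @ [1.5, -0.7, 0.3] + rng.normal(0, 0.5, 15)
        df = pd.DataFrame(np.column_stack([y, X]), columns=["y", "x", "c1", "c2"])
        fit = fit_adjusted_regression(df, "y", "x", covariates=["c1", "c2"])
        Xc = np.column_stack([np.ones(15), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        assert fit.estimate == pytest.approx(beta[1], abs=1e-8)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(25, 2)), columns=["y", "x"])
        fit = fit_adjusted_regression(df, "y", "x")
        assert fit.ci_low <= fit.estimate <= fit.ci_high

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(12, dtype=float)
        df = pd.DataFrame({"y": x, "x": x, "dup": 2 * x})
        with pytest.raises(ValueError, match="dup"):
            fit_adjusted_regression(df, "y", "x", covariates=["dup"])

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "x": [1.0, 2, 3], "z": [2.0, 1, 0]})
        with pytest.raises(ValueError, match="need n"):
            fit_adjusted_regression(df, "y", "x", covariates=["z"])
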