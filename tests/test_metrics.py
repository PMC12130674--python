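"""Tests of SMD/ASMD, matched-cohort effect estimation, and summaries."""

import math

import numpy as np
import pytest

from psdrs import (
    MatchedSet,
    NonEstimableError,
    RepResult,
    SeparationError,
    TRUE_LOG_OR,
    average_asmd,
    estimate_effect,
    greedy_match,
    relative_bias,
    simulate_cohort,
    smd_binary,
    smd_continuous,
    summarize,
)
from psdrs.cohort import BINARY_COLUMNS

from conftest import make_spec


class TestSMD:
    def test_unit_denominator(self):
        rng = np.random.default_rng(0)
        x_t = rng.standard_normal(100_000) + 1.0
        x_c = rng.standard_normal(100_000)
        assert smd_continuous(x_t, x_c) == pytest.approx(1.0, abs=0.02)

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        assert smd_continuous(x, x) == 0.0

    def test_hand_value_continuous(self):
        # means 0.3 vs 0.1, variances 0.04 each -> 0.2 / 0.2 = 1.0
        x_t = np.array([0.1, 0.3, 0.5])  # mean 0.3, var 0.04
        x_c = np.array([-0.1, 0.1, 0.3])  # mean 0.1, var 0.04
        assert smd_continuous(x_t, x_c) == pytest.approx(1.0)

    def test_zero_variance_unequal_means(self):
        assert math.isnan(smd_continuous(np.array([1.0, 1.0]), np.array([0.0, 0.0])))

    def test_binary_identity(self):
        assert smd_binary(0.5, 0.5) == 0.0

    def test_binary_hand_value(self):
        assert smd_binary(0.7, 0.5) == pytest.approx(0.2 / math.sqrt(0.23))

    def test_binary_degenerate(self):
        assert math.isnan(smd_binary(1.0, 0.0))
        assert smd_binary(1.0, 1.0) == 0.0

    def test_binary_domain(self):
        with pytest.raises(ValueError):
            smd_binary(1.2, 0.5)


def asmd_oracle(cohort, rows):
    """Independent column-by-column recomputation of the average |SMD|."""
    T = cohort.T[rows]
    X = cohort.X.iloc[rows]
    vals = []
    for col in X.columns:
        x_t = X[col].to_numpy()[T == 1]
        x_c = X[col].to_numpy()[T == 0]
        if col in BINARY_COLUMNS:
            p_t, p_c = x_t.mean(), x_c.mean()
            denom = math.sqrt((p_t * (1 - p_t) + p_c * (1 - p_c)) / 2)
            s = 0.0 if denom == 0 and p_t == p_c else (p_t - p_c) / denom if denom else math.nan
        else:
            num = x_t.mean() - x_c.mean()
            denom = math.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2)
            s = 0.0 if denom == 0 and num == 0 else num / denom if denom else math.nan
        if not math.isnan(s):
            vals.append(abs(s))
    return float(np.mean(vals))


class TestAverageASMD:
    def test_oracle_equivalence_random_cohorts(self):
        spec = make_spec(n=20, prevalence=0.4)
        for rep in range(5):
            cohort = simulate_cohort(spec, rep)
            if cohort.degenerate:
                continue
            rows = np.arange(cohort.n)
            assert average_asmd(cohort) == pytest.approx(asmd_oracle(cohort, rows), abs=1e-12)

    def test_matched_subset(self):
        cohort = simulate_cohort(make_spec(n=200, prevalence=0.3), 0)
        ps = np.clip(cohort.T * 0.1 + 0.45 + np.random.default_rng(0).normal(0, 0.02, cohort.n), 0.01, 0.99)
        m = greedy_match(ps, cohort.T, caliper_multiplier=10)
        got = average_asmd(cohort, m)
        assert got == pytest.approx(asmd_oracle(cohort, m.matched_rows()), abs=1e-12)

    def test_single_imbalanced_covariate(self, small_cohort):
        # build a two-group cohort whose groups are identical except one column
        import copy

        cohort = copy.copy(small_cohort)
        half = cohort.n // 2
        X = cohort.X.copy()
        X.iloc[half:] = X.iloc[:half].to_numpy()  # mirror covariates
        T = np.zeros(cohort.n, dtype=int)
        T[:half] = 1
        X.loc[X.index[:half], "X1"] = X["X1"].iloc[:half] + X["X1"].iloc[:half].std() * 0.5
        cohort.X, cohort.T = X, T
        got = average_asmd(cohort)
        assert got == pytest.approx(0.5 / 56, rel=1e-9)

    def test_requires_both_groups(self, small_cohort):
        with pytest.raises(NonEstimableError):
            average_asmd(small_cohort, np.flatnonzero(small_cohort.T == 1))

    def test_confounders_only_option(self, small_cohort):
        all56 = average_asmd(small_cohort)
        conf50 = average_asmd(small_cohort, covariates="confounders")
        assert all56 != conf50


def matched_all(cohort):
    return greedy_match(np.full(cohort.n, 0.5), cohort.T)


class TestEstimateEffect:
    def make_table_cohort(self, a, b, c, d):
        import copy

        n = a + b + c + d
        cohort = simulate_cohort(make_spec(n=max(n, 4), prevalence=0.5), 0)
        cohort = copy.copy(cohort)
        cohort.T = np.array([1] * (a + b) + [0] * (c + d))
        cohort.Y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        cohort.X = cohort.X.iloc[:n]
        return cohort

    def test_hand_two_by_two(self):
        cohort = self.make_table_cohort(30, 70, 15, 85)
        m = MatchedSet(pairs=list(zip(range(100), range(100, 200))), caliper_width=1.0,
                       score_kind="PS", unmatched_treated=0)
        est = estimate_effect(cohort, m)
        assert est == pytest.approx(math.log((30 * 85) / (70 * 15)), abs=1e-8)

    def test_null_table(self):
        cohort = self.make_table_cohort(20, 30, 20, 30)
        m = MatchedSet(pairs=list(zip(range(50), range(50, 100))), caliper_width=1.0,
                       score_kind="PS", unmatched_treated=0)
        assert estimate_effect(cohort, m) == pytest.approx(0.0, abs=1e-10)

    def test_zero_cell_raises_separation(self):
        cohort = self.make_table_cohort(10, 0, 5, 5)
        m = MatchedSet(pairs=list(zip(range(10), range(10, 20))), caliper_width=1.0,
                       score_kind="PS", unmatched_treated=0)
        with pytest.raises(SeparationError):
            estimate_effect(cohort, m)

    def test_haldane_option(self):
        cohort = self.make_table_cohort(10, 0, 5, 5)
        m = MatchedSet(pairs=list(zip(range(10), range(10, 20))), caliper_width=1.0,
                       score_kind="PS", unmatched_treated=0)
        est = estimate_effect(cohort, m, zero_cell="haldane")
        assert est == pytest.approx(math.log((10.5 * 5.5) / (0.5 * 5.5)))

    def test_regression_matches_closed_form_on_simulated_matches(self):
        cohort = simulate_cohort(make_spec(n=600, prevalence=0.3), 1)
        m = matched_all(cohort)
        a = np.sum((cohort.T[m.matched_rows()] == 1) & (cohort.Y[m.matched_rows()] == 1))
        b = np.sum((cohort.T[m.matched_rows()] == 1) & (cohort.Y[m.matched_rows()] == 0))
        c = np.sum((cohort.T[m.matched_rows()] == 0) & (cohort.Y[m.matched_rows()] == 1))
        d = np.sum((cohort.T[m.matched_rows()] == 0) & (cohort.Y[m.matched_rows()] == 0))
        assert estimate_effect(cohort, m) == pytest.approx(math.log(a * d / (b * c)), abs=1e-8)

    def test_empty_match_not_estimable(self, small_cohort):
        m = MatchedSet(pairs=[], caliper_width=0.1, score_kind="PS", unmatched_treated=3)
        with pytest.raises(NonEstimableError):
            estimate_effect(small_cohort, m)


class TestRelativeBias:
    @pytest.mark.parametrize(
        "est, expected",
        [(TRUE_LOG_OR, 0.0), (2 * TRUE_LOG_OR, 1.0), (0.0, 1.0)],
    )
    def test_closed_forms(self, est, expected):
        assert relative_bias(est) == pytest.approx(expected)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_bias(0.1, 0.0)


class TestBalanceImprovement:
    def test_ps_matching_improves_balance(self):
        # prevalence 0.5 with strong confounding: matched-cohort ASMD falls
        # below the raw-cohort ASMD in every replicate (scaled-down check)
        from psdrs import LearnerSpec, fit_propensity

        spec = make_spec(prevalence=0.5, n=2_000, base_seed=21)
        for rep in range(5):
            cohort = simulate_cohort(spec, rep)
            ps = fit_propensity(cohort, LearnerSpec("reference"), rep)
            matched = greedy_match(ps, cohort.T)
            assert average_asmd(cohort, matched) < average_asmd(cohort)


def rep(bias, **kw):
    defaults = dict(scenario_id=1, rep_index=0, score_kind="PS", learner="reference",
                    estimated_log_or=0.5, relative_bias=bias, asmd_pre=0.2,
                    asmd_post=0.05, brier=0.1, n_pairs=10)
    defaults.update(kw)
    return RepResult(**defaults)


class TestSummarize:
    def test_identical_values_zero_width_ci(self):
        s = summarize([rep(0.3, rep_index=i) for i in range(5)])
        assert s.mean_relative_bias == pytest.approx(0.3)
        assert s.relative_bias_ci == pytest.approx((0.3, 0.3))
        assert s.n_estimable == 5 and s.n_failed == 0

    def test_two_value_hand_ci(self):
        s = summarize([rep(0.0), rep(2.0, rep_index=1)])
        assert s.mean_relative_bias == pytest.approx(1.0)
        # SD = sqrt(2); CI half-width = 1.96 * sqrt(2)/sqrt(2) = 1.96
        lo, hi = s.relative_bias_ci
        assert lo == pytest.approx(1.0 - 1.959963984540054, abs=1e-9)
        assert hi == pytest.approx(1.0 + 1.959963984540054, abs=1e-9)

    def test_permutation_invariance(self):
        reps = [rep(b, rep_index=i) for i, b in enumerate([0.1, 0.9, 0.4, 0.7])]
        fwd = summarize(reps)
        rev = summarize(list(reversed(reps)))
        assert fwd.mean_relative_bias == pytest.approx(rev.mean_relative_bias, abs=1e-12)
        assert fwd.relative_bias_ci == pytest.approx(rev.relative_bias_ci, abs=1e-12)
        assert fwd.n_estimable == rev.n_estimable

    def test_failed_replicates_excluded_from_bias_not_asmd(self):
        good = [rep(0.2, rep_index=i) for i in range(3)]
        failed = rep(float("nan"), rep_index=3, estimated_log_or=float("nan"),
                     failure_reason="separation", asmd_post=0.5)
        s = summarize(good + [failed])
        assert s.n_estimable == 3 and s.n_failed == 1
        assert s.mean_relative_bias == pytest.approx(0.2)
        # the separation replicate still contributes its matched ASMD
        assert s.mean_asmd_post == pytest.approx((0.05 * 3 + 0.5) / 4)

    def test_sd_mode_widens_ci(self):
        reps = [rep(b, rep_index=i) for i, b in enumerate([0.0, 1.0, 2.0, 3.0])]
        se = summarize(reps, ci_mode="se").relative_bias_ci
        sd = summarize(reps, ci_mode="sd").relative_bias_ci
        assert sd[1] - sd[0] > se[1] - se[0]

    def test_single_estimable_flagged_unreliable(self):
        s = summarize([rep(0.2)])
        assert s.unreliable
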