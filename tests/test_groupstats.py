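import numpy as np
import pytest
from scipy import stats

from myoarray import (
    ValidationError,
    linear_regression,
    newman_keuls,
    one_way_anova,
    studentized_range_critical,
)

# 5% studentized-range critical values from standard published tables
# (span p, error df) -> q
Q_TABLE_5PCT = {
    (2, 10): 3.15, (2, 120): 2.80, (3, 27): 3.51, (3, 60): 3.40,
    (4, 30): 3.85, (5, 15): 4.37, (5, 20): 4.23, (6, 10): 4.91,
    (7, 40): 4.39, (8, 60): 4.44, (10, 12): 5.39, (10, 120): 4.56,
}


class TestOneWayAnova:
    def test_equal_means_f_zero(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_k2_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 8)
        res = one_way_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-12)

    def test_three_group_longhand(self, rng):
        groups = [np.array([0.0, 0.0]), np.array([1.0, 1.0]),
                  np.array([2.0, 2.0])]
        groups = [g + rng.normal(0, 1e-3, 2) for g in groups]
        res = one_way_anova(groups)
        # longhand sum-of-squares decomposition
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / 2) / (ssw / 3)
        assert res.f_statistic == pytest.approx(f, rel=1e-10)
        assert res.df_between == 2 and res.df_within == 3

    def test_degrees_of_freedom_and_mse(self, rng):
        groups = [rng.normal(0, 1, n) for n in (3, 4, 5)]
        res = one_way_anova(groups)
        assert res.df_between == 2 and res.df_within == 9
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert res.mse == pytest.approx(ssw / 9, rel=1e-12)

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1.0], [2.0, 3.0]])

    def test_null_p_values_uniform(self, rng):
        """ANOVA p under the null is Uniform(0,1) (KS check)."""
        ps = [one_way_anova([rng.normal(0, 1, 5) for _ in range(3)]).p_value
              for _ in range(600)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestStudentizedRange:
    def test_matches_published_5pct_tables(self):
        for (span, df), expected in Q_TABLE_5PCT.items():
            q = studentized_range_critical(span, df, 0.05)
            assert q == pytest.approx(expected, abs=0.005)


class TestNewmanKeuls:
    def test_identical_groups_nothing_significant(self):
        res = newman_keuls([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.significant_pairs() == []

    def test_k2_matches_pooled_t_decision(self, rng):
        """For two groups q = |t|*sqrt(2), so the decision equals the t-test's."""
        for _ in range(40):
            a = rng.normal(0, 1, int(rng.integers(3, 8)))
            b = rng.normal(rng.uniform(0, 2), 1, int(rng.integers(3, 8)))
            res = newman_keuls([a, b], alpha=0.05)
            t_p = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert (len(res.significant_pairs()) == 1) == (t_p < 0.05)
            comp = res.comparisons[0]
            t_abs = abs(stats.ttest_ind(a, b, equal_var=True).statistic)
            assert comp.q == pytest.approx(t_abs * np.sqrt(2), rel=1e-9)

    def test_three_group_step_down(self, rng):
        """Means (0, 0.1, 5.0), sd 1, n=10: extreme pairs significant, the
        close pair not; critical value at span 3, df 27 is the table's 3.51."""
        groups = [rng.normal(0.0, 1, 10), rng.normal(0.1, 1, 10),
                  rng.normal(5.0, 1, 10)]
        res = newman_keuls(groups, alpha=0.05)
        sig = set(res.significant_pairs())
        assert (0, 2) in sig and (1, 2) in sig
        assert (0, 1) not in sig
        span3 = [c for c in res.comparisons if c.span == 3][0]
        assert span3.q_critical == pytest.approx(3.51, abs=0.01)

    def test_nested_blocking(self, rng):
        """A non-significant spanning range blocks every nested pair, even a
        nested pair whose raw q would exceed its own critical value."""
        # three close means, one far: the span-3 range among the close ones
        # may be non-significant while nested span-2 q values fluctuate
        groups = [rng.normal(m, 1, 6) for m in (0.0, 0.4, 0.8, 10.0)]
        res = newman_keuls(groups, alpha=0.05)
        by_pair = {(c.group_i, c.group_j): c for c in res.comparisons}
        for c in res.comparisons:
            if c.blocked:
                assert not c.significant
        # blocking invariant: no significant pair nested inside a
        # non-significant range (in sorted-mean coordinates)
        means = [float(np.mean(g)) for g in groups]
        order = np.argsort(means)
        pos = {g: i for i, g in enumerate(order)}
        spans = {(min(pos[c.group_i], pos[c.group_j]),
                  max(pos[c.group_i], pos[c.group_j])): c.significant
                 for c in res.comparisons}
        for (lo, hi), sig in spans.items():
            if not sig:
                for (lo2, hi2), sig2 in spans.items():
                    if lo <= lo2 and hi2 <= hi and (lo2, hi2) != (lo, hi):
                        assert not sig2

    def test_unbalanced_groups_accepted(self, rng):
        groups = [rng.normal(0, 1, 7), rng.normal(0, 1, 8), rng.normal(3, 1, 7)]
        res = newman_keuls(groups, alpha=0.05)
        assert len(res.comparisons) == 3

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValidationError):
            newman_keuls([[1.0, 2.0], [3.0, 4.0]], alpha=1.5)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_matches_scipy_linregress(self, rng):
        x = rng.normal(0, 1, 30)
        y = 0.7 * x + rng.normal(0, 1, 30)
        res = linear_regression(x, y)
        ref = stats.linregress(x, y)
        assert res.slope == pytest.approx(ref.slope, rel=1e-10)
        assert res.r == pytest.approx(ref.rvalue, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_independent_noise_small_r(self, rng):
        x, y = rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)
        res = linear_regression(x, y)
        assert abs(res.r) < 0.1

    def test_negating_y_flips_sign_same_p(self, rng):
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        res1, res2 = linear_regression(x, y), linear_regression(x, -y)
        assert res2.slope == pytest.approx(-res1.slope)
        assert res2.r == pytest.approx(-res1.r)
        assert res2.p_value == pytest.approx(res1.p_value)

    def test_constant_x_rejected_constant_y_warns(self):
        with pytest.raises(ValidationError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning):
            res = linear_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.slope == 0.0 and res.r == 0.0
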