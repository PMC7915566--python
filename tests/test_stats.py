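import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dvjmech.stats import (StatsError, icc_3_1, paired_power, paired_t,
                           percent_change, required_sample_size,
                           rm_anova_oneway)
from dvjmech.stats import test_retest_reliability as reliability


class TestReliability:
    def test_identical_visits_report_perfect_reliability(self):
        v = np.array([2.0, 2.0, 2.0, 2.0])
        rep = reliability(v, v)
        assert rep.cv_pct == 0.0
        assert rep.sem == 0.0
        assert rep.icc == 1.0
        assert rep.degenerate

    def test_icc_matches_explicit_mean_squares(self, rng):
        """Brute-force two-way ANOVA decomposition reproduces ICC(3,1)."""
        data = rng.integers(1, 30, size=(5, 2)).astype(float)
        n, k = data.shape
        grand = data.mean()
        ss_rows = k * ((data.mean(1) - grand) ** 2).sum()
        ss_cols = n * ((data.mean(0) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_rows - ss_cols
        msr = ss_rows / (n - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        oracle = (msr - mse) / (msr + (k - 1) * mse)
        assert icc_3_1(data) == pytest.approx(oracle, abs=1e-12)

    def test_icc_cross_checked_against_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        data = rng.normal(50, 10, size=(8, 2)) + rng.normal(
            0, 2, size=(8, 2))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 2),
            "rater": np.tile([0, 1], 8),
            "score": data.reshape(-1),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
        sel = table["Type"].isin(["ICC3", "ICC(C,1)"])
        ref = float(table.loc[sel, "ICC"].iloc[0])
        assert icc_3_1(data) == pytest.approx(ref, abs=1e-9)

    def test_cv_definition(self):
        v1 = np.array([10.0, 20.0])
        v2 = np.array([12.0, 18.0])
        # per-subject SD/mean*100: (sqrt(2)/11)*100 and (sqrt(2)/19)*100
        expected = np.mean([np.std([10, 12], ddof=1) / 11 * 100,
                            np.std([20, 18], ddof=1) / 19 * 100])
        rep = reliability(v1, v2)
        assert rep.cv_pct == pytest.approx(expected, abs=1e-12)

    def test_zero_mean_with_spread_undefined(self):
        with pytest.raises(StatsError, match="undefined"):
            reliability(np.array([1.0, -1.0]),
                                    np.array([-1.0, 1.0]))

    def test_icc_recovers_variance_ratio(self, rng):
        """Mean ICC over simulated panels approaches the between/(between +
        error) variance ratio (small-sample estimator bias < 0.005 at a
        10:1 variance ratio)."""
        sigma_b, sigma_e, n = 10.0, 1.0, 13
        truth = sigma_b**2 / (sigma_b**2 + sigma_e**2)
        est = []
        for _ in range(400):
            subj = rng.normal(0, sigma_b, n)
            data = subj[:, None] + rng.normal(0, sigma_e, (n, 2))
            est.append(icc_3_1(data))
        se = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est) - truth) < max(3 * se, 0.005)


class TestRmAnova:
    def test_two_timepoints_equals_squared_paired_t(self, rng):
        for _ in range(10):
            data = rng.normal(size=(7, 2))
            f, df1, df2, p = rm_anova_oneway(data)
            t, df, p_t, _ = paired_t(data[:, 0], data[:, 1])
            assert f == pytest.approx(t**2, abs=1e-12)
            assert p == pytest.approx(p_t, abs=1e-12)

    def test_all_equal_values(self):
        f, _, _, p = rm_anova_oneway(np.full((6, 3), 4.2))
        assert f == 0.0
        assert p == 1.0

    def test_cross_checked_against_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        data = rng.normal(size=(9, 4)) + np.array([0, 0.5, 1.0, 0.3])
        f, df1, df2, p = rm_anova_oneway(data)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(9), 4),
            "time": np.tile(np.arange(4), 9),
            "y": data.reshape(-1),
        })
        ref = pg.rm_anova(data=long, dv="y", within="time",
                          subject="subject")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(StatsError, match="complete"):
            rm_anova_oneway(data)


class TestPairedT:
    def test_identical_samples(self):
        t, df, p, md = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (t, p, md) == (0.0, 1.0, 0.0)
        assert df == 2

    def test_constant_shift_degenerate_branch(self):
        t, df, p, md = paired_t([1.0, 2, 3], [2.0, 3, 4])
        assert np.isinf(t) and t > 0
        assert p == 0.0
        assert md == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(20):
            a = rng.normal(size=9)
            b = rng.normal(size=9)
            t, df, p, md = paired_t(a, b)
            d = b - a
            t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(9))
            assert t == pytest.approx(t_ref, abs=1e-12)
            ref = sps.ttest_rel(b, a)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (2.04, 1.79, -12.3),
        (0.077, 0.055, -28.6),
        (3.02, 2.53, -16.2),
        (100.0, 80.5, -19.5),
        (313.2, 381.7, 21.9),
    ])
    def test_printed_values(self, pre, post, expected):
        assert round(percent_change(pre, post), 1) == expected

    def test_identity(self):
        assert percent_change(5.0, 5.0) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(pre=st.floats(0.1, 1e3), post=st.floats(-1e3, 1e3),
           c=st.floats(0.01, 100))
    def test_invariant_to_common_scaling(self, pre, post, c):
        assert percent_change(pre, post) == pytest.approx(
            percent_change(c * pre, c * post), rel=1e-9, abs=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(StatsError):
            percent_change(0.0, 1.0)


class TestPower:
    def test_large_n_limit(self):
        assert paired_power(1.05, 10_000) > 0.9999

    def test_monotone_in_n(self):
        powers = [paired_power(0.6, n) for n in range(2, 101)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_matches_monte_carlo_rejection_rate(self, rng):
        d, n, alpha, reps = 1.05, 12, 0.05, 200_000
        x = rng.normal(d, 1.0, size=(reps, n))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        tcrit = sps.t.isf(alpha / 2, n - 1)
        mc = np.mean(np.abs(t) > tcrit)
        assert paired_power(d, n, alpha) == pytest.approx(mc, abs=0.005)

    def test_required_sample_size_threshold(self):
        n = required_sample_size(1.05, power=0.8)
        assert paired_power(1.05, n) >= 0.8
        assert paired_power(1.05, n - 1) < 0.8

    def test_unreachable_power_rejected(self):
        with pytest.raises(StatsError, match="not reachable"):
            required_sample_size(1e-4, power=0.99, n_max=50)
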