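import numpy as np
import pytest
from scipy import stats as sps

from dyadnet import (
    NormBand,
    PowerQuery,
    ReferenceNorm,
    compare_to_reference,
    ks_normality,
    one_way_anova,
    power_min_r,
    rm_anova,
    tukey_hsd,
)
from dyadnet.classical_stats import DegenerateDataError, correlation_power


def rm_anova_oracle(y):
    """Brute-force sum-of-squares decomposition, written independently."""
    n, t = y.shape
    grand = y.mean()
    ss_time = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(t))
    ss_subj = sum(t * (y[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(t))
    ms_time = ss_time / (t - 1)
    ms_err = (ss_tot - ss_time - ss_subj) / ((t - 1) * (n - 1))
    return ms_time / ms_err


class TestKSNormality:
    def test_single_point_against_standard_normal(self):
        res = ks_normality(np.array([0.0]), mean=0.0, sd=1.0)
        assert res.statistic == pytest.approx(0.5)

    def test_uniform_sample_rejected_against_fitted_normal(self):
        rng = np.random.default_rng(0)
        res = ks_normality(rng.uniform(0, 1, size=1000))
        assert res.p_value < 0.01

    def test_p_values_uniform_under_fixed_reference_null(self):
        """With a known (not fitted) reference the K-S p-value is U(0,1)."""
        rng = np.random.default_rng(1)
        pvals = [
            ks_normality(rng.normal(0, 1, size=1000), mean=0.0, sd=1.0).p_value
            for _ in range(200)
        ]
        d, p = sps.kstest(pvals, "uniform")
        assert p > 0.05

    def test_zero_variance_sample_errors(self):
        with pytest.raises(DegenerateDataError):
            ks_normality(np.ones(10))


class TestRMAnova:
    def test_zero_time_effect_gives_zero_F(self):
        rng = np.random.default_rng(2)
        subj = rng.normal(size=6)
        noise = rng.normal(size=(6, 3))
        y = subj[:, None] + noise
        y = y - y.mean(axis=0, keepdims=True)  # remove time effect exactly
        res = rm_anova(y)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_oracle(self):
        y = np.array(
            [[3.0, 5.0, 4.0], [2.0, 4.0, 6.0], [5.0, 7.0, 8.0], [1.0, 2.0, 3.0]]
        )
        res = rm_anova(y)
        assert res.statistic == pytest.approx(rm_anova_oracle(y), rel=1e-12)
        assert res.df == (2, 6)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        y = rng.normal(size=(8, 3)) + np.arange(3) * 0.5
        res = rm_anova(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "time": np.tile(np.arange(3), 8),
                "y": y.ravel(),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="time", subject="subject")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_identical_columns_plus_offsets_degenerate(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.column_stack([base, base, base])
        with pytest.raises(DegenerateDataError):
            rm_anova(y)


class TestTukey:
    def test_equal_means_q_zero_p_one(self):
        results = tukey_hsd(np.array([2.0, 2.0, 2.0]), 1.0, 5, 12.0)
        assert all(r.statistic == 0 for r in results)
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_matches_direct_formula(self):
        means = np.array([1.0, 2.5, 4.0])
        ms, n, df = 2.0, 6, 15.0
        results = tukey_hsd(means, ms, n, df)
        q01 = abs(means[0] - means[1]) / np.sqrt(ms / n)
        r01 = next(r for r in results if r.label == "tukey:g0-g1")
        assert r01.statistic == pytest.approx(q01, rel=1e-12)
        assert r01.p_value == pytest.approx(
            sps.studentized_range.sf(q01, 3, df), rel=1e-9
        )

    def test_p_monotone_decreasing_in_q(self):
        qs = [tukey_hsd(np.array([0.0, d]), 1.0, 5, 10.0)[0] for d in (0.5, 1.0, 2.0)]
        ps = [r.p_value for r in qs]
        assert ps[0] > ps[1] > ps[2]

    def test_invariant_to_group_relabeling(self):
        means = np.array([1.0, 3.0, 2.0])
        a = sorted(r.p_value for r in tukey_hsd(means, 1.5, 4, 9.0))
        b = sorted(r.p_value for r in tukey_hsd(means[::-1].copy(), 1.5, 4, 9.0))
        assert a == pytest.approx(b)


class TestOneWayAnova:
    def test_hand_decomposition(self):
        res = one_way_anova([np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])])
        assert res.statistic == pytest.approx(1.5, rel=1e-12)

    def test_two_group_F_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        res = one_way_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_null_groups_large_p(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        res = one_way_anova(groups)
        assert res.p_value > 0.01

    def test_all_constant_groups_degenerate(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova([np.ones(3), np.full(3, 2.0)])


class TestPowerMinR:
    def test_study_sample_size_gives_printed_value(self):
        r = power_min_r(PowerQuery(n=16, alpha=0.05, power=0.8, sides="two"))
        assert r == pytest.approx(0.63, abs=0.02)

    def test_r_vanishes_as_power_approaches_alpha(self):
        rs = [
            power_min_r(PowerQuery(n=16, alpha=0.05, power=pw))
            for pw in (0.3, 0.1, 0.06, 0.051)
        ]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.05

    def test_monotone_decreasing_in_n(self):
        rs = [power_min_r(PowerQuery(n=n)) for n in (10, 16, 30, 100)]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_power_verified_by_monte_carlo_at_n_100(self):
        """The returned r really yields ~80% rejections of the exact t-test
        for zero correlation over simulated bivariate-normal samples."""
        n = 100
        r = power_min_r(PowerQuery(n=n))
        rng = np.random.default_rng(6)
        L = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
        reject = 0
        reps = 4000
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ L.T
            rhat = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            t = rhat * np.sqrt((n - 2) / (1 - rhat**2))
            if abs(t) > sps.t.ppf(0.975, n - 2):
                reject += 1
        assert reject / reps == pytest.approx(0.8, abs=0.02)

    def test_agrees_with_plain_fisher_z_for_moderate_n(self):
        for n in (30, 60, 120):
            q = PowerQuery(n=n)
            df = n - 2
            tcrit = sps.t.ppf(0.975, df)
            rcrit = tcrit / np.sqrt(df + tcrit**2)
            closed = np.tanh(
                np.arctanh(rcrit) + sps.norm.ppf(0.8) / np.sqrt(n - 3)
            )
            assert power_min_r(q) == pytest.approx(closed, abs=0.03)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            PowerQuery(n=3)

    def test_power_function_increasing_in_r(self):
        q = PowerQuery(n=20)
        ps = [correlation_power(r, q) for r in (0.1, 0.3, 0.5, 0.7)]
        assert all(a < b for a, b in zip(ps, ps[1:]))


class TestReferenceNorm:
    norm = ReferenceNorm("Anxiety", 4.25, 3.53)

    @pytest.mark.parametrize(
        "mean,band",
        [
            (4.25, NormBand.within_1sd),
            (7.79, NormBand.above_1sd),
            (7.7, NormBand.within_1sd),
            (0.5, NormBand.below),
        ],
    )
    def test_band_classification(self, mean, band):
        assert compare_to_reference(mean, self.norm) == band

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            ReferenceNorm("Anxiety", 4.25, 0.0)
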