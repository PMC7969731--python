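"""Statistics battery against closed forms and independent implementations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from awakerest import stats as st


class TestBinomialTest:
    def test_ten_of_twelve_matches_printed_values(self):
        res = st.binomial_test_two_sided(10, 12)
        assert res.p == pytest.approx(158 / 4096)
        assert round(res.p, 3) == 0.039
        assert res.cohens_g == pytest.approx(1 / 3)

    def test_eleven_of_twelve(self):
        res = st.binomial_test_two_sided(11, 12)
        assert round(res.p, 3) == 0.006
        assert round(res.cohens_g, 3) == 0.417

    def test_symmetric_center_gives_p_one(self):
        res = st.binomial_test_two_sided(6, 12)
        assert res.p == 1.0
        assert res.cohens_g == 0.0

    def test_all_successes_matches_enumeration(self):
        res = st.binomial_test_two_sided(12, 12)
        assert res.p == pytest.approx(2 / 4096)

    @pytest.mark.parametrize("k,n", [(0, 7), (3, 9), (8, 15), (10, 20)])
    def test_matches_scipy_exact_test(self, k, n):
        ours = st.binomial_test_two_sided(k, n).p
        theirs = sps.binomtest(k, n, 0.5).pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestTTests:
    def test_one_sample_closed_form(self):
        x = np.array([0.6, 0.7, 0.8])
        res = st.one_sample_t(x, 0.5)
        # by hand: mean 0.7, sd 0.1, se 0.1/sqrt(3), t = 0.2*sqrt(3)/0.1
        assert res.t == pytest.approx(0.2 * np.sqrt(3) / 0.1)
        assert res.df == 2
        ref = sps.ttest_1samp(x, 0.5)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.effect_size == pytest.approx(2.0)  # Cohen's d = 0.2/0.1

    def test_identical_paired_samples_give_zero_variance_error(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            st.paired_t(x, x)

    def test_paired_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 15))
        res = st.paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_independent_and_welch_match_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 3, 10)
        for equal_var in (True, False):
            res = st.independent_t(x, y, equal_var=equal_var)
            ref = sps.ttest_ind(x, y, equal_var=equal_var)
            assert res.t == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_hedges_g_is_corrected_cohens_d(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1, 1, 10)
        y = rng.normal(0, 1, 10)
        res = st.independent_t(x, y)
        sp = np.sqrt((9 * x.var(ddof=1) + 9 * y.var(ddof=1)) / 18)
        d = (x.mean() - y.mean()) / sp
        assert res.effect_size == pytest.approx(d * (1 - 3 / (4 * 18 - 1)))

    def test_welch_df_never_exceeds_pooled_df(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(3, 20, size=2)
            x = rng.normal(0, rng.uniform(0.5, 3), n1)
            y = rng.normal(0, rng.uniform(0.5, 3), n2)
            res = st.independent_t(x, y, equal_var=False)
            assert res.df <= n1 + n2 - 2 + 1e-9


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((10, 2))
        eff = st.rm_anova_one_way(y)
        t = st.paired_t(y[:, 0], y[:, 1])
        assert eff.F == pytest.approx(t.t**2, abs=1e-10)
        assert eff.p_uncorrected == pytest.approx(t.p, abs=1e-10)

    def test_constant_scores_give_zero_effect(self):
        eff = st.rm_anova_one_way(np.full((6, 3), 2.5))
        assert eff.ss_effect == 0.0
        assert eff.partial_eta_sq == 0.0

    def test_one_way_matches_pingouin(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((12, 3)) + np.array([0.0, 0.3, 0.1])
        eff = st.rm_anova_one_way(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "level": np.tile(np.arange(3), 12),
                "score": y.ravel(),
            }
        )
        ref = pg.rm_anova(
            data=long, dv="score", within="level", subject="subject", detailed=True
        )
        assert eff.F == pytest.approx(ref.loc[0, "F"], rel=1e-9)
        assert eff.p_uncorrected == pytest.approx(ref.loc[0, "p_unc"], rel=1e-9)
        assert eff.ss_effect == pytest.approx(ref.loc[0, "SS"], rel=1e-9)
        assert eff.partial_eta_sq == pytest.approx(
            ref.loc[0, "SS"] / (ref.loc[0, "SS"] + ref.loc[1, "SS"]), rel=1e-9
        )
        # sphericity machinery against pingouin's
        sph = pg.sphericity(long, dv="score", within="level", subject="subject")
        assert eff.mauchly_w == pytest.approx(sph.W, rel=1e-9)
        assert eff.mauchly_p == pytest.approx(sph.pval, rel=1e-6)
        eps = pg.epsilon(long, dv="score", within="level", subject="subject", correction="hf")
        assert eff.hf_epsilon == pytest.approx(min(1.0, eps), rel=1e-6)

    def test_two_way_matches_pingouin(self):
        rng = np.random.default_rng(6)
        n, a, b = 12, 3, 3
        y = rng.standard_normal((n, a, b))
        y += np.array([0.0, 0.25, 0.05])[None, :, None]  # time effect
        res = st.rm_anova_two_way(y, ("time", "region"))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), a * b),
                "time": np.tile(np.repeat(np.arange(a), b), n),
                "region": np.tile(np.arange(b), n * a),
                "score": y.ravel(),
            }
        )
        ref = pg.rm_anova(
            data=long,
            dv="score",
            within=["time", "region"],
            subject="subject",
            detailed=True,
        ).set_index("Source")
        for name, row in (
            ("time", "time"),
            ("region", "region"),
            ("time*region", "time * region"),
        ):
            eff = res[name]
            assert eff.F == pytest.approx(ref.loc[row, "F"], rel=1e-9), name
            assert eff.p_uncorrected == pytest.approx(
                ref.loc[row, "p_unc"], rel=1e-9
            ), name
            assert eff.df_num == ref.loc[row, "ddof1"]
            assert eff.df_den == ref.loc[row, "ddof2"]
            assert eff.ss_effect == pytest.approx(ref.loc[row, "SS"], rel=1e-9)
            # partial eta squared is consistent with its own F and dfs
            assert eff.partial_eta_sq == pytest.approx(
                eff.F * eff.df_num / (eff.F * eff.df_num + eff.df_den), rel=1e-9
            )

    def test_missing_cells_rejected(self):
        y = np.ones((5, 3, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            st.rm_anova_two_way(y)

    def test_type_one_error_rate_calibrated(self):
        """Exchangeable (compound-symmetric) null data: the sphericity-policy
        p-value rejects at close to the nominal 5% rate."""
        rng = np.random.default_rng(7)
        n, k, reps = 10, 3, 2000
        rejections = 0
        for _ in range(reps):
            subject = rng.standard_normal((n, 1))
            y = subject + rng.standard_normal((n, k))
            if st.rm_anova_one_way(y).p < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065


class TestTrendContrast:
    def test_peak_at_middle_is_pure_quadratic(self):
        y = np.tile([0.0, 1.0, 0.0], (8, 1))  # noise-free peaked profile
        assert np.isinf(st.polynomial_trend_contrast(y, order=2).F)
        assert st.polynomial_trend_contrast(y, order=1).F == 0.0

    def test_linear_profile_has_zero_quadratic(self):
        y = np.tile([0.0, 0.5, 1.0], (8, 1))
        assert st.polynomial_trend_contrast(y, order=2).F == 0.0

    def test_equals_squared_paired_t_on_contrast_scores(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((12, 3))
        quad = st.polynomial_trend_contrast(y, order=2)
        c = np.array([1.0, -2.0, 1.0]) / np.sqrt(6.0)
        scores = y @ c
        t = st.one_sample_t(scores, 0.0)
        assert quad.F == pytest.approx(t.t**2, rel=1e-10)
        assert quad.p == pytest.approx(t.p, rel=1e-10)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            st.polynomial_trend_contrast(np.ones((5, 2)), order=2)


class TestDixon:
    def test_extreme_outlier_flagged(self):
        res = st.dixon_q_test([1.0, 1.0, 1.0, 10.0])
        assert res.q_exp == pytest.approx(1.0)
        assert res.outlier

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            st.dixon_q_test([2.0, 2.0, 2.0, 2.0])

    def test_gap_over_range_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.standard_normal(12)
            res = st.dixon_q_test(x)
            s = np.sort(x)
            expected = max(s[1] - s[0], s[-1] - s[-2]) / (s[-1] - s[0])
            assert res.q_exp == pytest.approx(expected, abs=1e-12)
            assert res.q_crit == 0.426  # r10, n = 12, alpha .05

    def test_unsupported_n_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            st.dixon_q_test([1.0, 2.0])


class TestMedianSplit:
    def test_simple_split(self):
        res = st.median_split_compare(
            scores=[0.0, 0.2, 1.0, 1.2], covariate=[1.0, 2.0, 3.0, 4.0]
        )
        assert sorted(res.lower_idx.tolist()) == [0, 1]
        assert res.upper_mean - res.lower_mean == pytest.approx(1.0)

    def test_invariant_to_monotone_covariate_transform(self):
        rng = np.random.default_rng(9)
        cov = rng.uniform(0.1, 2.0, 12)
        scores = rng.standard_normal(12)
        a = st.median_split_compare(scores, cov)
        b = st.median_split_compare(scores, np.log(cov))
        assert set(a.lower_idx.tolist()) == set(b.lower_idx.tolist())
        assert a.test.t == pytest.approx(b.test.t)

    def test_odd_n_puts_median_subject_in_lower_group(self):
        res = st.median_split_compare(
            scores=np.arange(5.0), covariate=[1.0, 2.0, 3.0, 4.0, 5.0]
        )
        assert sorted(res.lower_idx.tolist()) == [0, 1, 2]

    def test_planted_association_detected_with_high_power(self):
        """Suppression depth proportional to improvement: the split detects
        the group difference in most 12-subject cohorts (strong effect)."""
        rng = np.random.default_rng(10)
        detected = 0
        cohorts = 100
        for _ in range(cohorts):
            improvement = rng.normal(0.3, 0.12, 12)
            suppression = 0.5 - 0.5 * improvement + rng.normal(0, 0.02, 12)
            res = st.median_split_compare(suppression, improvement)
            detected += res.test.p < 0.05
        assert detected / cohorts > 0.8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            st.median_split_compare([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0])


class TestAssumptionChecks:
    def test_ks_calibrated_under_true_null(self):
        """Fully specified normal null: rejection near the nominal rate."""
        rng = np.random.default_rng(11)
        rejections = sum(
            st.ks_normality(rng.standard_normal(1000), mean=0.0, sd=1.0).p < 0.05
            for _ in range(200)
        )
        assert 0.01 <= rejections / 200 <= 0.10

    def test_ks_statistic_matches_scipy(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(100)
        ours = st.ks_normality(x, mean=0.0, sd=1.0)
        ref = sps.kstest(x, "norm")
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_levene_detects_tenfold_variance_ratio(self):
        rng = np.random.default_rng(13)
        rejections = sum(
            st.levene_test(rng.normal(0, 1, 50), rng.normal(0, np.sqrt(10), 50)).p
            < 0.05
            for _ in range(100)
        )
        assert rejections == 100

    def test_levene_matches_scipy(self):
        rng = np.random.default_rng(14)
        x, y = rng.standard_normal((2, 30))
        ours = st.levene_test(x, y, center="mean")
        ref = sps.levene(x, y, center="mean")
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_mauchly_calibrated_under_sphericity(self):
        rng = np.random.default_rng(15)
        rejections = 0
        for _ in range(300):
            y = rng.standard_normal((15, 1)) + rng.standard_normal((15, 4))
            rejections += st.mauchly_test(y).p < 0.05
        assert 0.02 <= rejections / 300 <= 0.10

    def test_battery_dispatch(self):
        rng = np.random.default_rng(16)
        out = st.assumption_checks(
            rng.standard_normal(30),
            groups=(rng.standard_normal(20), rng.standard_normal(20)),
            repeated=rng.standard_normal((10, 3)),
        )
        assert set(out) == {"ks_normality", "levene", "mauchly"}
        assert all(0.0 <= v.p <= 1.0 for v in out.values())
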