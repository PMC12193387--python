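"""Group-comparison statistics: ANCOVA, t-tests, two-factor ANOVA."""

import numpy as np
import pytest
from scipy import stats as sps

from fpturnover import (
    compare_halflives_ttest,
    compare_peaks,
    compare_slopes_ancova,
    halflife_anova,
    simulate_daily_decay,
    simulate_halflife_table,
    windowed_ln_points,
)
from fpturnover.errors import DataError, DegenerateStatisticsWarning


def lnpoints(hl, seed=None, cv=0.10, n=6):
    t, v = simulate_daily_decay(hl, n_days=n, noise_cv=cv, seed=seed)
    return t, np.log(v)


class TestAncova:
    def test_identical_groups_give_f_zero_p_one(self):
        t = np.arange(6.0)
        lnf = np.log(1000.0) - 0.2 * t + np.sin(t) * 0.05  # not collinear
        res = compare_slopes_ancova({"a": (t, lnf), "b": (t, lnf)})
        assert res.interaction_F == 0.0
        assert res.p_value == 1.0

    def test_noiseless_lines_with_different_slopes(self):
        t = np.arange(6.0)
        with pytest.warns(DegenerateStatisticsWarning):
            res = compare_slopes_ancova(
                {"a": (t, -0.2 * t), "b": (t, -0.4 * t)}
            )
        assert res.p_value == pytest.approx(0.0)
        assert res.degenerate

    def test_reported_slopes_are_per_group_ols_slopes(self):
        ta, la = lnpoints(3.5, seed=1)
        tb, lb = lnpoints(17.0, seed=2)
        res = compare_slopes_ancova({"ctrl": (ta, la), "btz": (tb, lb)})
        assert res.slopes["ctrl"] == pytest.approx(float(sps.linregress(ta, la).slope))
        assert res.slopes["btz"] == pytest.approx(float(sps.linregress(tb, lb).slope))
        assert res.df == (1, 8)

    def test_group_with_too_few_points_named_in_error(self):
        with pytest.raises(DataError, match="tiny"):
            compare_slopes_ancova(
                {"ok": (np.arange(4.0), np.arange(4.0)),
                 "tiny": (np.array([0.0, 1.0]), np.array([0.0, -1.0]))}
            )

    def test_two_group_f_matches_textbook_formula(self):
        # hand computation via separate-fits residuals
        rng = np.random.default_rng(3)
        t = np.arange(6.0)
        la = -0.25 * t + rng.normal(0, 0.05, 6)
        lb = -0.40 * t + rng.normal(0, 0.05, 6)
        res = compare_slopes_ancova({"a": (t, la), "b": (t, lb)})
        # full model = two separate lines
        ra = la - np.polyval(np.polyfit(t, la, 1), t)
        rb = lb - np.polyval(np.polyfit(t, lb, 1), t)
        ss_full = (ra**2).sum() + (rb**2).sum()
        # reduced model: common slope, group intercepts
        x = np.concatenate([t, t])
        y = np.concatenate([la, lb])
        g = np.concatenate([np.zeros(6), np.ones(6)])
        X = np.column_stack([np.ones(12), x, g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        ss_red = ((y - X @ beta) ** 2).sum()
        f_hand = (ss_red - ss_full) / (ss_full / 8)
        assert res.interaction_F == pytest.approx(f_hand, rel=1e-10)

    def test_type_I_error_near_nominal(self):
        # equal true slopes, cv 10%, 6 points per group, alpha 0.05
        n_rej = 0
        n_sims = 400
        for seed in range(n_sims):
            res = compare_slopes_ancova(
                {"a": lnpoints(3.5, seed=2 * seed),
                 "b": lnpoints(3.5, seed=2 * seed + 1)}
            )
            n_rej += res.p_value < 0.05
        assert 0.02 <= n_rej / n_sims <= 0.09

    def test_power_to_separate_slow_from_fast_decay(self):
        # control-like vs proteasome-inhibited-like half-lives
        n_rej = 0
        for seed in range(100):
            res = compare_slopes_ancova(
                {"ctrl": lnpoints(3.5, seed=50_000 + 2 * seed),
                 "btz": lnpoints(17.0, seed=50_000 + 2 * seed + 1)}
            )
            n_rej += res.p_value < 0.05
        assert n_rej / 100 >= 0.8


class TestTTest:
    def test_identical_groups(self):
        t, df, p = compare_halflives_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == 1.0

    def test_large_shift_is_significant(self):
        t, df, p = compare_halflives_ttest([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_swapping_groups_negates_t_preserves_p(self):
        a, b = [3.1, 3.9, 4.4], [6.8, 7.1, 8.0]
        t1, _, p1 = compare_halflives_ttest(a, b)
        t2, _, p2 = compare_halflives_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_pooled_option_matches_scipy_equal_var(self):
        a, b = [3.0, 4.0, 5.0], [4.0, 6.0, 9.0]
        t, df, p = compare_halflives_ttest(a, b, equal_var=True)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert (t, p) == pytest.approx((ref.statistic, ref.pvalue))
        assert df == 4

    def test_insufficient_n_rejected(self):
        with pytest.raises(DataError):
            compare_halflives_ttest([1.0], [1.0, 2.0])

    def test_p_matches_permutation_test_on_small_samples(self):
        rng = np.random.default_rng(12)
        a = rng.normal(4.0, 1.0, 6)
        b = rng.normal(5.5, 1.0, 6)
        t_obs, _, p_welch = compare_halflives_ttest(a, b)
        perm = sps.permutation_test(
            (a, b),
            lambda x, y, axis=-1: sps.ttest_ind(x, y, equal_var=False, axis=axis).statistic,
            permutation_type="independent", n_resamples=5000,
            alternative="two-sided", rng=0,
        )
        assert p_welch == pytest.approx(perm.pvalue, abs=0.03)


class TestHalflifeAnova:
    def test_constant_response_flagged_convention(self):
        tab = simulate_halflife_table(3, residual_sd=0.0, seed=0)
        with pytest.warns(DegenerateStatisticsWarning):
            aov = halflife_anova(tab)
        assert aov.loc["age_group", "F"] == 0.0
        assert aov.loc["age_group", "p"] == 1.0

    def test_pure_age_effect_detected_sex_not(self):
        tab = simulate_halflife_table(10, effects={"age": 2.5},
                                      residual_sd=0.5, seed=42)
        aov = halflife_anova(tab)
        assert aov.loc["age_group", "p"] < 0.01
        assert aov.loc["sex", "p"] > 0.01  # no sex effect simulated

    def test_sequential_equals_type2_on_balanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        tab = simulate_halflife_table(6, effects={"age": 1.0, "sex": 0.5},
                                      residual_sd=0.4, seed=5)
        aov1 = halflife_anova(tab)
        model = smf.ols("half_life ~ C(age_group) * C(sex)", data=tab).fit()
        aov2 = sm.stats.anova_lm(model, typ=2)
        assert aov1.loc["age_group", "sum_sq"] == pytest.approx(
            aov2.loc["C(age_group)", "sum_sq"]
        )
        assert aov1.loc["sex", "sum_sq"] == pytest.approx(
            aov2.loc["C(sex)", "sum_sq"]
        )

    def test_null_p_values_roughly_uniform(self):
        pvals = []
        for seed in range(120):
            tab = simulate_halflife_table(5, residual_sd=0.5, seed=seed)
            pvals.append(halflife_anova(tab).loc["sex", "p"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_level_factor_rejected(self):
        tab = simulate_halflife_table(3, seed=0)
        tab = tab[tab["sex"] == "male"]
        with pytest.raises(DataError):
            halflife_anova(tab)

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(DataError, match="missing columns"):
            halflife_anova(pd.DataFrame({"half_life": [1, 2]}))


class TestComparePeaks:
    def test_identical_peaks_not_significant(self):
        t, p = compare_peaks([10.0, 11.0, 9.0], [10.0, 11.0, 9.0])
        assert p == 1.0

    def test_three_fold_separation_significant(self):
        t, p = compare_peaks([10.0, 10.5, 9.5, 10.2], [30.0, 31.0, 29.5, 30.8])
        assert p < 0.01

    def test_single_vial_rejected(self):
        with pytest.raises(DataError):
            compare_peaks([10.0], [12.0, 13.0])
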