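"""Mixed RM-ANCOVA machinery: sphericity, calibration, oracles, contrasts."""

import numpy as np
import pandas as pd
import pytest

from blinkcr.stats import (
    bonferroni_adjust,
    gg_epsilon,
    helmert_contrasts,
    mauchly_test,
    mixed_rm_ancova,
    one_way_anova,
    two_sample_t,
)


def _null_design(rng, n=40):
    a = np.repeat([True, False], n // 2)
    b = np.tile(np.repeat([True, False], n // 4), 2)
    age = rng.normal(48, 11, n)
    return a, b, age


class TestMauchly:
    def test_two_levels_forced_unity(self):
        rng = np.random.default_rng(0)
        res = mauchly_test(rng.normal(size=(20, 2)))
        assert res.W == 1.0 and res.p == 1.0

    def test_df_formula(self):
        rng = np.random.default_rng(0)
        assert mauchly_test(rng.normal(size=(40, 6))).df == 14

    def test_type_i_rate_under_compound_symmetry(self):
        rng = np.random.default_rng(1)
        rej = 0
        reps = 2000
        for _ in range(reps):
            Y = rng.normal(size=(40, 6)) + rng.normal(size=(40, 1))
            rej += mauchly_test(Y).p < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_power_under_heterogeneity(self):
        rng = np.random.default_rng(2)
        scale = np.array([0.3, 0.6, 1.0, 1.5, 2.2, 3.0])
        rej = 0
        for _ in range(500):
            Y = rng.normal(size=(40, 1)) + rng.normal(size=(40, 6)) * scale
            rej += mauchly_test(Y).p < 0.05
        assert rej / 500 > 0.8

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(25, 5)) * np.array([1, 1, 2, 1, 3.0])
        mine = mauchly_test(Y)
        ref = pg.sphericity(pd.DataFrame(Y))
        assert mine.W == pytest.approx(ref.W, rel=1e-8)
        assert mine.chi_sq == pytest.approx(ref.chi2, rel=1e-8)
        assert mine.p == pytest.approx(ref.pval, rel=1e-6)

    def test_insufficient_subjects(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mauchly_test(rng.normal(size=(4, 6)))


class TestGgEpsilon:
    def test_two_levels_forced(self):
        rng = np.random.default_rng(0)
        assert gg_epsilon(rng.normal(size=(20, 2))) == 1.0

    def test_spherical_population_near_one(self):
        rng = np.random.default_rng(4)
        assert gg_epsilon(rng.normal(size=(500, 4))) > 0.95

    def test_rank_one_attains_lower_bound(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(200, 1))
        Y = v @ np.array([[1.0, 2, 3, 4, 5, 6]]) + 1e-9 * rng.normal(size=(200, 6))
        assert gg_epsilon(Y) == pytest.approx(0.2, abs=1e-6)

    def test_bounds_on_random_data(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            Y = rng.normal(size=(rng.integers(k + 2, 40), k))
            eps = gg_epsilon(Y)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(30, 5)) * np.array([1, 1, 2, 1, 3.0])
        assert gg_epsilon(Y) == pytest.approx(
            float(pg.epsilon(pd.DataFrame(Y), correction="gg")), rel=1e-8
        )


class TestMixedAncova:
    def test_balanced_toy_matches_ss_oracle(self):
        """F values equal the classical split-plot cell-means decomposition."""
        Y = np.array(
            [[3.0, 5, 7], [4, 6, 9], [2, 5, 6], [5, 7, 8],
             [6, 9, 12], [7, 8, 10], [1, 2, 3], [4, 4, 6]]
        )
        a = np.array([True] * 4 + [False] * 4)
        b = np.array([True, True, False, False] * 2)
        res = mixed_rm_ancova(Y, a, b, None)
        oracle = _split_plot_oracle(Y, a, b)
        for eff, f_expected in oracle.items():
            assert res.table.loc[eff, "F"] == pytest.approx(f_expected, abs=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(16, 4))
        a, b, age = _null_design(rng, 16)
        f1 = mixed_rm_ancova(Y, a, b, age).table["F"]
        f2 = mixed_rm_ancova(Y + 100.0, a, b, age).table["F"]
        assert np.allclose(f1, f2)

    def test_reported_df_match_study_design(self):
        """n=54 with two factors and age: between df 1,49; within 5,245."""
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(54, 6))
        a = rng.uniform(size=54) < 0.5
        a[:4], a[-4:] = True, False
        b = np.tile([True, False], 27)
        res = mixed_rm_ancova(Y, a, b, rng.normal(48, 11, 54))
        assert res.table.loc["PTSD", "df_den"] == 49
        assert res.table.loc["Block", "df_num"] == 5
        assert res.table.loc["Block", "df_den"] == 245

    def test_type_i_rates_under_null(self):
        rng = np.random.default_rng(10)
        reps = 2000
        effects = ["PTSD", "mTBI", "PTSD:mTBI", "Block", "Block:PTSD"]
        rej = dict.fromkeys(effects, 0)
        for _ in range(reps):
            Y = rng.normal(size=(40, 6)) + rng.normal(size=(40, 1))
            a, b, age = _null_design(rng)
            table = mixed_rm_ancova(Y, a, b, age).table
            for eff in effects:
                rej[eff] += table.loc[eff, "p_uncorrected"] < 0.05
        for eff in effects:
            assert 0.035 <= rej[eff] / reps <= 0.065, (eff, rej[eff] / reps)

    def test_gg_correction_never_anticonservative(self):
        """Shrinking both dfs by epsilon <= 1 raises the p of any effect in
        the rejection-relevant region; for F near or below 1 the correction
        can move either way, so only that region is asserted."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(100):
            Y = rng.normal(size=(24, 5)) * rng.uniform(0.5, 2.0, size=5)
            a, b, age = _null_design(rng, 24)
            res = mixed_rm_ancova(Y, a, b, age, gg_policy="always")
            within = res.table[
                (res.table["df_num"] > 1) & (res.table["p_uncorrected"] < 0.10)
            ]
            checked += len(within)
            assert (within["p_gg"] >= within["p_uncorrected"] - 1e-12).all()
        assert checked >= 20

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(12)
        Y = rng.normal(size=(12, 3))
        a = np.array([True] * 6 + [False] * 6)
        b = np.array([True] * 6 + [False] * 6)  # no (T,F) or (F,T) cells
        with pytest.raises(ValueError):
            mixed_rm_ancova(Y, a, b, None)

    def test_collinear_covariate_rejected(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(16, 3))
        a, b, _ = _null_design(rng, 16)
        with pytest.raises(ValueError):
            mixed_rm_ancova(Y, a, b, np.ones(16))

    def test_partial_eta_sq_in_unit_interval(self):
        rng = np.random.default_rng(14)
        Y = rng.normal(size=(20, 4)) + np.where(
            np.repeat([True, False], 10), 2.0, 0.0
        )[:, None]
        a, b, age = _null_design(rng, 20)
        res = mixed_rm_ancova(Y, a, b, age)
        assert ((res.table["partial_eta_sq"] >= 0)
                & (res.table["partial_eta_sq"] <= 1)).all()


def _split_plot_oracle(Y, a, b):
    """Classical balanced split-plot SS decomposition via cell means."""
    n, k = Y.shape
    grand = Y.mean()
    sm = Y.mean(1)
    ybj = Y.mean(0)
    half, quarter = n // 2, n // 4
    ssA = sum(half * k * (sm[a == lv].mean() - grand) ** 2 for lv in (True, False))
    ssB = sum(half * k * (sm[b == lv].mean() - grand) ** 2 for lv in (True, False))
    ssAB = sum(
        quarter * k * (
            sm[(a == la) & (b == lb)].mean()
            - sm[a == la].mean() - sm[b == lb].mean() + grand
        ) ** 2
        for la in (True, False) for lb in (True, False)
    )
    ss_subj = k * np.sum((sm - grand) ** 2)
    ss_err_b = ss_subj - ssA - ssB - ssAB
    ms_err_b = ss_err_b / (n - 4)
    ssBl = n * np.sum((ybj - grand) ** 2)
    ssBlA = sum(
        half * np.sum((Y[a == lv].mean(0) - Y[a == lv].mean() - ybj + grand) ** 2)
        for lv in (True, False)
    )
    ssBlB = sum(
        half * np.sum((Y[b == lv].mean(0) - Y[b == lv].mean() - ybj + grand) ** 2)
        for lv in (True, False)
    )
    ssBlAB = 0.0
    for la in (True, False):
        for lb in (True, False):
            cell = Y[(a == la) & (b == lb)]
            term = (
                cell.mean(0) - Y[a == la].mean(0) - Y[b == lb].mean(0) + ybj
                - (cell.mean() - Y[a == la].mean() - Y[b == lb].mean() + grand)
            )
            ssBlAB += quarter * np.sum(term**2)
    ssT = np.sum((Y - grand) ** 2)
    ss_err_w = ssT - ss_subj - ssBl - ssBlA - ssBlB - ssBlAB
    ms_err_w = ss_err_w / ((n - 4) * (k - 1))
    return {
        "PTSD": ssA / ms_err_b,
        "mTBI": ssB / ms_err_b,
        "PTSD:mTBI": ssAB / ms_err_b,
        "Block": ssBl / (k - 1) / ms_err_w,
        "Block:PTSD": ssBlA / (k - 1) / ms_err_w,
        "Block:mTBI": ssBlB / (k - 1) / ms_err_w,
        "Block:PTSD:mTBI": ssBlAB / (k - 1) / ms_err_w,
    }


class TestBonferroni:
    def test_examples(self):
        assert bonferroni_adjust([0.01], m=3) == [pytest.approx(0.03)]
        assert bonferroni_adjust([0.5], m=4) == [1.0]
        assert bonferroni_adjust([0.2, 0.7], m=1) == [pytest.approx(0.2),
                                                      pytest.approx(0.7)]

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])


class TestTTestAndAnova:
    def test_identical_samples(self):
        t, df, p = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_pooled_df_matches_reported(self):
        rng = np.random.default_rng(15)
        t, df, p = two_sample_t(rng.normal(size=20), rng.normal(size=14))
        assert df == 32

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(16)
        x, y = rng.normal(size=12), rng.normal(1.0, 1, 15)
        t, df, p_t = two_sample_t(x, y)
        F, (d1, d2), p_f, _ = one_way_anova([x, y])
        assert F == pytest.approx(t**2, rel=1e-10)
        assert (d1, d2) == (1, df)
        assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_scipy_cross_check(self):
        from scipy import stats as sps
        rng = np.random.default_rng(17)
        x, y = rng.normal(size=10), rng.normal(0.5, 1, 12)
        t, df, p = two_sample_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestHelmert:
    def test_contrast_estimates(self):
        low = np.zeros(5) + 1e-9 * np.arange(5)
        mid = np.ones(5) + 1e-9 * np.arange(5)
        high = np.ones(5) + 2e-9 * np.arange(5)
        c1, c2 = helmert_contrasts([low, mid, high])
        assert c1.estimate == pytest.approx(-1.0, abs=1e-6)
        assert c2.estimate == pytest.approx(0.0, abs=1e-6)

    def test_estimates_match_weighted_means(self):
        rng = np.random.default_rng(18)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 8), (1, 11), (3, 6))]
        c1, c2 = helmert_contrasts(groups)
        m = [g.mean() for g in groups]
        assert c1.estimate == pytest.approx(m[0] - (m[1] + m[2]) / 2, abs=1e-10)
        assert c2.estimate == pytest.approx(m[1] - m[2], abs=1e-10)

    def test_type_i_rate_equal_means(self):
        rng = np.random.default_rng(19)
        rej = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(size=12) for _ in range(3)]
            c1, _ = helmert_contrasts(groups)
            rej += c1.p < 0.05
        assert 0.035 <= rej / reps <= 0.065

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            helmert_contrasts([np.ones(3), np.ones(3)])
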