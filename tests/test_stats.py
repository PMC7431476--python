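import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surveylearn.stats import (
    MixedAnova,
    SummaryStat,
    bonferroni,
    cohens_d_pooled,
    cohens_d_z,
    fisher_z,
    fisher_z_inverse,
    independent_t_from_summary,
    one_sample_t,
    paired_t,
    polynomial_contrasts,
    trend_contrasts,
)


def long_frame(y: np.ndarray, groups, subjects=None):
    """Build a long table from a subjects x sessions matrix."""
    n, k = y.shape
    subjects = subjects or [f"s{i}" for i in range(n)]
    rows = [
        {"participant_id": subjects[i], "condition": groups[i], "session": s + 1,
         "value": y[i, s]}
        for i in range(n) for s in range(k)
    ]
    return pd.DataFrame(rows)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_known_value(self):
        assert fisher_z(0.91) == pytest.approx(math.atanh(0.91), abs=1e-12)
        assert fisher_z(0.91) == pytest.approx(1.5275, abs=1e-4)

    @given(r=st.floats(-0.999, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_strictly_increasing_odd(self, r):
        assert fisher_z_inverse(fisher_z(r)) == pytest.approx(r, abs=1e-12)
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        if r < 0.99:
            assert fisher_z(r + 0.005) > fisher_z(r)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestEffectSizes:
    def test_condition_contrast_reproduces_printed_d(self):
        d = cohens_d_pooled(SummaryStat(52.32, 17.66, 20), SummaryStat(39.57, 12.70, 20))
        assert d == pytest.approx(0.83, abs=0.005)

    def test_group_vs_average_reproduces_printed_d(self):
        d = cohens_d_pooled(SummaryStat(52.32, 17.66, 20), SummaryStat(27.06, 17.89, 20))
        assert d == pytest.approx(1.42, abs=0.005)

    def test_identical_groups_zero(self):
        s = SummaryStat(5.0, 2.0, 10)
        assert cohens_d_pooled(s, s) == 0.0

    def test_agrees_with_raw_data_counterpart(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 2, 15), rng.normal(0, 2, 12)
        d_summary = cohens_d_pooled(SummaryStat.from_values(a), SummaryStat.from_values(b))
        pooled = math.sqrt(((14) * a.std(ddof=1) ** 2 + 11 * b.std(ddof=1) ** 2) / 25)
        assert d_summary == pytest.approx((a.mean() - b.mean()) / pooled)

    def test_d_z_from_diffs(self):
        diffs = [1.0, 2.0, 0.5, 1.5]
        assert cohens_d_z(diffs) == pytest.approx(
            abs(np.mean(diffs)) / np.std(diffs, ddof=1))


class TestTTests:
    def test_feedback_vs_average_printed_values(self):
        t, df, p = independent_t_from_summary(
            SummaryStat(52.32, 17.66, 20), SummaryStat(27.06, 17.89, 20))
        assert t == pytest.approx(4.49, abs=0.01)
        assert df == 38
        assert p < 0.001

    def test_card_rotations_cohort_comparison(self):
        t, df, p = independent_t_from_summary(
            SummaryStat(100.35, 33.56, 40), SummaryStat(110.48, 33.77, 452))
        assert t == pytest.approx(-1.82, abs=0.01)
        assert df == 490

    def test_equal_means_null(self):
        t, df, p = independent_t_from_summary(
            SummaryStat(5, 1, 10), SummaryStat(5, 1, 10))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_raw_data(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 14), rng.normal(0.5, 1, 17)
        t, df, p = independent_t_from_summary(
            SummaryStat.from_values(a), SummaryStat.from_values(b))
        t_ref, p_ref = sps.ttest_ind(a, b)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_one_sample_printed_ratio_example(self):
        t, df, p, d_z = one_sample_t(SummaryStat(1.02, 0.30, 20), 1.0)
        assert t == pytest.approx(0.298, abs=0.001)
        assert df == 19
        assert d_z == pytest.approx(0.0667, abs=0.001)

    def test_one_sample_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x = rng.normal(1.1, 0.4, 25)
        t, df, p, _ = one_sample_t(x, 1.0)
        t_ref, p_ref = sps.ttest_1samp(x, 1.0)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_one_sample_degenerate_sd(self):
        t, df, p, d_z = one_sample_t(SummaryStat(2.0, 0.0, 5), 1.0)
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_paired_t_is_one_sample_on_diffs(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 12)
        b = a + rng.normal(0.4, 0.5, 12)
        t, df, p, _ = paired_t(a, b)
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)


class TestBonferroni:
    def test_adjustment_and_decisions(self):
        out = bonferroni([0.01, 0.04, 0.5], m=3)
        assert list(out["p_adj"]) == pytest.approx([0.03, 0.12, 1.0])
        assert list(out["significant"]) == [True, False, False]

    def test_m_must_cover_tests(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)

    def test_p_range_checked(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestPolynomialContrasts:
    def test_six_level_coefficients_match_standard_table(self):
        c = polynomial_contrasts(6)
        np.testing.assert_array_equal(c[1], [-5, -3, -1, 1, 3, 5])
        np.testing.assert_array_equal(c[2], [5, -1, -4, -4, -1, 5])
        np.testing.assert_array_equal(c[3], [-5, 7, 4, -4, -7, 5])

    @pytest.mark.parametrize("k", [3, 4, 5, 6, 7])
    def test_zero_sum_and_pairwise_orthogonal(self, k):
        cs = polynomial_contrasts(k, orders=range(1, k))
        for c in cs.values():
            assert abs(c.sum()) < 1e-9
        keys = list(cs)
        for i, ki in enumerate(keys):
            for kj in keys[i + 1:]:
                assert abs(np.dot(cs[ki], cs[kj])) < 1e-8

    def test_order_must_fit_levels(self):
        with pytest.raises(ValueError):
            polynomial_contrasts(3, orders=(3,))


class TestMixedAnova:
    def test_all_identical_values_give_zero_f(self):
        y = np.full((6, 4), 3.0)
        df = long_frame(y, ["A"] * 3 + ["B"] * 3)
        res = MixedAnova.from_dataframe(df).fit()
        for eff in ("condition", "session", "session:condition"):
            assert res.effect(eff)["F"] == 0.0

    def test_toy_design_matches_hand_computed_ss(self):
        # 2 conditions x 2 subjects each x 2 sessions; sums of squares worked
        # out by hand from the split-plot formulas
        y = np.array([[1.0, 3.0], [2.0, 4.0], [5.0, 7.0], [6.0, 10.0]])
        df = long_frame(y, ["A", "A", "B", "B"])
        res = MixedAnova.from_dataframe(df).fit()
        assert res.effect("condition")["ss"] == pytest.approx(40.5)
        assert res.effect("subjects(condition)")["ss"] == pytest.approx(5.0)
        assert res.effect("session")["ss"] == pytest.approx(12.5)
        assert res.effect("session:condition")["ss"] == pytest.approx(0.5)
        assert res.effect("residual")["ss"] == pytest.approx(1.0)
        assert res.effect("condition")["F"] == pytest.approx(16.2)
        assert res.effect("session")["F"] == pytest.approx(25.0)
        assert res.effect("session:condition")["F"] == pytest.approx(1.0)
        assert res.effect("condition")["partial_eta_sq"] == pytest.approx(40.5 / 45.5)
        assert res.effect("session")["partial_eta_sq"] == pytest.approx(12.5 / 13.5)

    def test_ss_conservation_on_random_designs(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n, k = int(rng.integers(3, 7)), int(rng.integers(2, 7))
            y = rng.normal(0, 2, size=(2 * n, k))
            df = long_frame(y, ["A"] * n + ["B"] * n)
            res = MixedAnova.from_dataframe(df).fit()
            total = float(((y - y.mean()) ** 2).sum())
            assert res.ss_total == pytest.approx(total, rel=1e-8)

    def test_agrees_with_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(23)
        y = rng.normal(0, 1, size=(12, 5)) + np.linspace(0, 1, 5)
        y[6:] += 0.7
        df = long_frame(y, ["A"] * 6 + ["B"] * 6)
        mine = MixedAnova.from_dataframe(df).fit()
        ref = pg.mixed_anova(df, dv="value", within="session",
                             subject="participant_id", between="condition")
        ref = ref.set_index("Source")
        for eff, src in (("condition", "condition"), ("session", "session"),
                         ("session:condition", "Interaction")):
            row = mine.effect(eff)
            assert row["F"] == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            assert row["p"] == pytest.approx(ref.loc[src, "p_unc"], rel=1e-9)
            assert row["partial_eta_sq"] == pytest.approx(ref.loc[src, "np2"], rel=1e-9)

    def test_condition_effect_recovered_session_effect_null(self):
        rng = np.random.default_rng(29)
        n = 20
        y = rng.normal(0, 1, size=(2 * n, 6))
        y[n:] += 1.0  # pure condition main effect
        df = long_frame(y, ["A"] * n + ["B"] * n)
        res = MixedAnova.from_dataframe(df).fit()
        assert res.effect("condition")["F"] > 10
        assert res.effect("session")["F"] < 3  # near its null expectation of ~1

    def test_unbalanced_design_rejected(self):
        y = np.ones((4, 3))
        df = long_frame(y, ["A", "A", "B", "B"]).iloc[:-1]
        with pytest.raises(ValueError, match="missing cells|exactly one"):
            MixedAnova.from_dataframe(df).fit()

    def test_single_subject_per_condition_rejected(self):
        y = np.ones((2, 3))
        with pytest.raises(ValueError, match="at least 2 subjects"):
            MixedAnova.from_dataframe(long_frame(y, ["A", "B"])).fit()

    def test_gg_epsilon_in_valid_range(self):
        rng = np.random.default_rng(31)
        y = rng.normal(0, 1, size=(10, 6))
        df = long_frame(y, ["A"] * 5 + ["B"] * 5)
        eps = MixedAnova.from_dataframe(df).fit().gg_epsilon
        assert 1 / 5 <= eps <= 1.0


class TestTrendContrasts:
    def test_linear_means_zero_quadratic_cubic_ss(self):
        # session means exactly linear, no subject noise in the trend direction
        n, k = 8, 6
        base = np.arange(1, k + 1, dtype=float)
        y = np.tile(base, (n, 1)) + np.arange(n)[:, None] * 0.1
        df = long_frame(y, ["A"] * 4 + ["B"] * 4)
        t = trend_contrasts(df).set_index("order")
        assert t.loc["linear", "ss"] > 0
        assert t.loc["quadratic", "ss"] == pytest.approx(0.0, abs=1e-16)
        assert t.loc["cubic", "ss"] == pytest.approx(0.0, abs=1e-16)

    def test_matches_contrast_regression_oracle(self):
        # oracle: OLS of per-subject contrast scores on a sum-coded group
        # factor; the intercept t-test is the trend test
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(37)
        n, k = 10, 6
        y = rng.normal(0, 1, size=(2 * n, k)) + np.linspace(0, 2, k)
        df = long_frame(y, ["A"] * n + ["B"] * n)
        mine = trend_contrasts(df).set_index("order")
        coeffs = polynomial_contrasts(k)
        for order, name in ((1, "linear"), (2, "quadratic"), (3, "cubic")):
            L = y @ coeffs[order]
            d = pd.DataFrame({"L": L, "g": ["A"] * n + ["B"] * n})
            fit = smf.ols("L ~ C(g, Sum)", data=d).fit()
            t_ref = fit.tvalues["Intercept"]
            assert mine.loc[name, "F"] == pytest.approx(t_ref**2, rel=1e-9)
            assert mine.loc[name, "df2"] == 2 * n - 2

    def test_single_group_trend(self):
        rng = np.random.default_rng(41)
        n, k = 12, 6
        y = rng.normal(0, 1, size=(n, k)) + np.linspace(0, 1.5, k)
        df = long_frame(y, ["only"] * n)
        t = trend_contrasts(df, between=None).set_index("order")
        assert t.loc["linear", "df2"] == n - 1
        assert t.loc["linear", "F"] > 4

    def test_pooled_error_variant_runs(self):
        rng = np.random.default_rng(43)
        y = rng.normal(0, 1, size=(8, 6))
        df = long_frame(y, ["A"] * 4 + ["B"] * 4)
        t = trend_contrasts(df, error="pooled").set_index("order")
        assert (t["df2"] == 6 * 5).all()  # (N - a)(k - 1) = 6 * 5
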