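import numpy as np
import pandas as pd
import pytest

from gstride.stats import (CohortTable, correlation_band, correlation_matrix,
                           describe_by_group, group_compare, icc_band,
                           icc_consistency, impute_median, ks_normality,
                           substitute_outliers)


def _icc_anova_oracle(data: np.ndarray) -> float:
    """From-scratch two-way ANOVA consistency ICC, written independently."""
    n, k = data.shape
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - grand) ** 2).sum() \
        - msr * (n - 1) - msc * (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestImputation:
    def test_median_fill(self):
        df = pd.DataFrame({"id": list("abcd"), "x": [1.0, 2.0, np.nan, 4.0],
                           "FALLS": [0, 0, 1, 1]})
        out = impute_median(df, ["x"])
        assert out.df.loc[2, "x"] == 2.0
        assert len(out.log) == 1 and out.log[0]["variable"] == "x"

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = impute_median(df, ["x"])
        assert out.df.equals(df) and out.log == []

    def test_all_missing_raises(self):
        df = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="x"):
            impute_median(df, ["x"])

    def test_blanked_cells_logged_exactly_and_others_untouched(self, cohort_df):
        """Blanking 60 cells (~0.66% of the table) yields exactly 60 log
        entries and leaves every other cell unchanged."""
        df = cohort_df.copy()
        num_cols = ["TUG", "FES1", "SPPB_Total", "Speed_4m_walk"]
        rng = np.random.default_rng(0)
        blanked = set()
        while len(blanked) < 60:
            blanked.add((int(rng.integers(len(df))), num_cols[int(rng.integers(4))]))
        for i, c in blanked:
            df.loc[i, c] = np.nan
        out = impute_median(df, num_cols)
        assert len(out.log) == 60
        edited = {(e["row"], e["variable"]) for e in out.log}
        assert edited == blanked
        for c in num_cols:
            untouched = [i for i in df.index if (i, c) not in blanked]
            pd.testing.assert_series_equal(out.df.loc[untouched, c],
                                           cohort_df.loc[untouched, c])


class TestOutlierSubstitution:
    def test_single_violation_replaced_by_valid_median(self):
        df = pd.DataFrame({"Speed_4m_walk": [0.8, 0.9, 2.4]})
        out = substitute_outliers(df)
        assert out.df["Speed_4m_walk"].tolist() == [0.8, 0.9, pytest.approx(0.85)]
        assert len(out.log) == 1

    def test_no_violation_is_identity(self):
        df = pd.DataFrame({"Speed_4m_walk": [0.8, 0.9, 1.1]})
        out = substitute_outliers(df)
        assert out.df.equals(df) and out.log == []

    def test_unknown_variable_in_rule_raises(self):
        df = pd.DataFrame({"x": [1.0]})
        with pytest.raises(ValueError):
            substitute_outliers(df, {"nope": lambda s: s < 1})


class TestNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(1).normal(0, 1, 5000)
        p, ok = ks_normality(x)
        assert ok

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(1).exponential(1.0, 5000)
        p, ok = ks_normality(x)
        assert not ok and p < 0.01

    def test_constant_vector_convention(self):
        with pytest.warns(UserWarning):
            p, ok = ks_normality(np.ones(20))
        assert p == 0.0 and not ok

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.arange(5))


class TestGroupCompare:
    def test_chi_squared_on_printed_sex_counts(self):
        """2x2 sex-by-group counts reproduce the published p = 0.10."""
        df = pd.DataFrame({
            "Sex": ["M"] * 26 + ["F"] * 51 + ["M"] * 19 + ["F"] * 67,
            "FALLS": [False] * 77 + [True] * 86})
        name, stat, p = group_compare(df, "Sex")
        assert name == "chi-squared"
        assert round(p, 2) == 0.10

    def test_chi_squared_on_printed_living_site_counts(self):
        df = pd.DataFrame({
            "Living_Site": ["H"] * 55 + ["R"] * 22 + ["H"] * 55 + ["R"] * 31,
            "FALLS": [False] * 77 + [True] * 86})
        _, _, p = group_compare(df, "Living_Site")
        assert round(p, 1) == 0.3

    def test_identical_groups_wilcoxon_p_near_one(self):
        vals = np.arange(30.0)
        df = pd.DataFrame({"x": np.concatenate([vals, vals]),
                           "FALLS": [False] * 30 + [True] * 30})
        name, _, p = group_compare(df, "x")
        assert name == "wilcoxon-rank-sum"
        assert p > 0.99

    def test_student_t_option(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(0, 1, 40),
                           "FALLS": [False] * 20 + [True] * 20})
        name, _, p = group_compare(df, "x", continuous_test="ttest")
        assert name == "student-t" and 0 <= p <= 1

    def test_empty_group_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "FALLS": [True, True]})
        with pytest.raises(ValueError):
            group_compare(df, "x")


class TestDescriptives:
    def test_constant_variable_cells(self):
        df = pd.DataFrame({"x": [5.0] * 10, "FALLS": [False] * 5 + [True] * 5})
        row = describe_by_group(df, "x")
        assert row.overall == "5.0 (0.0)/[5.0|5.0]"
        assert row.fallers == "5.0 (0.0)/[5.0|5.0]"

    def test_categorical_cells_count_over_group_size(self):
        df = pd.DataFrame({"Sex": ["M", "F", "F", "F"],
                           "FALLS": [False, False, True, True]})
        row = describe_by_group(df, "Sex")
        assert row.fallers["F"] == "2/2 (100%)"
        assert row.nonfallers["M"] == "1/2 (50%)"

    def test_configured_effect_direction(self, cohort_df):
        g = cohort_df.groupby("FALLS")["Velocity (m/s)"].mean()
        assert g[True] < g[False]


class TestIcc:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        res = icc_consistency(np.c_[x, x])
        assert res.icc == pytest.approx(1.0)

    def test_fixed_offset_ignored(self):
        x = np.random.default_rng(3).normal(0, 1, 20)
        res = icc_consistency(np.c_[x, x + 5.0])
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle(self, rng):
        for _ in range(50):
            data = rng.normal(0, 1, (10, 2)) + rng.normal(0, 1, (10, 1))
            res = icc_consistency(data)
            assert res.icc == pytest.approx(_icc_anova_oracle(data), abs=1e-10)

    def test_matches_pingouin_icc_c1(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(0, 1, (15, 2)) + rng.normal(0, 1, (15, 1))
        res = icc_consistency(data)
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(15), 2),
            "raters": np.tile([0, 1], 15),
            "ratings": data.ravel()})
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings")
        row = ref[ref.Type == "ICC(C,1)"].iloc[0]
        assert res.icc == pytest.approx(row.ICC, abs=1e-8)
        assert res.f_statistic == pytest.approx(row.F, abs=1e-8)
        assert (res.df1, res.df2) == (row.df1, row.df2)

    def test_scale_invariance(self, rng):
        data = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1, (12, 1))
        a = icc_consistency(data).icc
        b = icc_consistency(data * 3.7).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_contains_estimate_and_band_consistent(self, rng):
        data = rng.normal(0, 1, (30, 2)) + 2 * rng.normal(0, 1, (30, 1))
        res = icc_consistency(data)
        assert res.ci95[0] <= res.icc <= res.ci95[1]
        assert res.band == icc_band(res.icc)
        assert res.icc <= 1.0

    def test_band_thresholds(self):
        assert icc_band(0.95) == "very good"
        assert icc_band(0.885) == "good"
        assert icc_band(0.6) == "moderate"
        assert icc_band(0.4) == "mediocre"
        assert icc_band(0.1) == "bad/null"


class TestCorrelations:
    def test_variable_with_itself_strong(self, cohort_df):
        cm = correlation_matrix(cohort_df, ["TUG"], ["TUG"])
        assert cm.r.loc["TUG", "TUG"] == 1.0
        assert cm.band.loc["TUG", "TUG"] == "strong"

    def test_skewed_variable_routes_to_spearman(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"gauss": rng.normal(0, 1, 300),
                           "skewed": rng.exponential(1.0, 300)})
        cm = correlation_matrix(df, ["gauss"], ["skewed"])
        assert cm.method.loc["gauss", "skewed"] == "spearman"

    def test_bivariate_normal_recovers_rho(self):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        df = pd.DataFrame({"a": z[:, 0], "b": z[:, 1]})
        cm = correlation_matrix(df, ["a"], ["b"])
        assert cm.method.loc["a", "b"] == "pearson"
        assert cm.r.loc["a", "b"] == pytest.approx(0.6, abs=0.05)
        assert cm.band.loc["a", "b"] == "strong"

    def test_symmetry_under_swap(self, cohort_df):
        va, vb = ["TUG", "FES1"], ["Speed_4m_walk", "SPPB_Total"]
        ab = correlation_matrix(cohort_df, va, vb)
        ba = correlation_matrix(cohort_df, vb, va)
        for x in va:
            for y in vb:
                assert ab.r.loc[x, y] == pytest.approx(ba.r.loc[y, x], abs=1e-12)

    def test_constant_variable_null_band(self):
        df = pd.DataFrame({"c": np.ones(20), "x": np.arange(20.0)})
        with pytest.warns(UserWarning):
            cm = correlation_matrix(df, ["c"], ["x"])
        assert np.isnan(cm.r.loc["c", "x"])
        assert cm.band.loc["c", "x"] == "null"

    def test_too_few_pairs_raises(self):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0)})
        with pytest.raises(ValueError):
            correlation_matrix(df, ["a"], ["b"])

    def test_band_thresholds(self):
        assert correlation_band(-0.7) == "strong"
        assert correlation_band(0.35) == "moderate"
        assert correlation_band(0.15) == "weak"
        assert correlation_band(0.05) == "null"


class TestCohortTable:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            CohortTable(pd.DataFrame({"id": ["a", "a"]}))
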