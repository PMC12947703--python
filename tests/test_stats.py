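"""Effect sizes, Welch t, balanced ANOVA, correlations, and correlation PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ricewue as rw
from ricewue.errors import ConfigError, DegenerateDataError, UnbalancedDesignError
from ricewue.stats import cohens_d, welch_t


def long_table(cells, trait="y"):
    """Build a TraitTable from {(treatment, subspecies): [values]}."""
    rows = []
    for (trt, sub), values in cells.items():
        for i, v in enumerate(values, start=1):
            rows.append(["G%s%d" % (sub[0], i), sub, trt, "T1", i, trait, 0, v])
    return rw.TraitTable(pd.DataFrame(
        rows, columns=["genotype", "subspecies", "treatment", "trial",
                       "replicate", "trait", "week", "value"]))


class TestCohensD:
    def test_hand_computed_example(self):
        # means 2 and 3, pooled sd exactly 1 -> d = -1
        r = cohens_d([1, 2, 3], [2, 3, 4])
        assert r.d == pytest.approx(-1.0)
        assert r.pooled_sd == pytest.approx(1.0)

    def test_identical_groups_give_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).d == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([0.0, 0.0], [0.0, 0.0])

    def test_single_value_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            cohens_d([1.0], [1.0, 2.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(n1=st.integers(2, 20), n2=st.integers(2, 20), seed=st.integers(0, 10**6))
    def test_hedges_ratio_identity(self, n1, n2, seed):
        """hedges_g / d equals 1 - 3/(4N - 9) exactly for any groups."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, n1), rng.normal(1, 2, n2)
        r = cohens_d(a, b)
        assert r.hedges_g / r.d == pytest.approx(1 - 3 / (4 * (n1 + n2) - 9))

    def test_pooled_sd_formula(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(size=12)
        r = cohens_d(a, b)
        expected = np.sqrt((6 * a.std(ddof=1) ** 2 + 11 * b.std(ddof=1) ** 2) / 17)
        assert r.pooled_sd == pytest.approx(expected, rel=1e-12)


class TestEffectSizesByTrait:
    def test_planted_positive_effect_has_positive_sign(self, table, truth):
        effects = {e.trait: e for e in rw.effect_sizes_by_trait(table)}
        # CEW is planted to increase under LW, gs to decrease
        assert effects["CEW"].d > 0
        assert effects["gs"].d < 0

    def test_genotype_mean_level_uses_one_value_per_genotype(self, table):
        effects = {e.trait: e for e in rw.effect_sizes_by_trait(table)}
        assert effects["gs"].n_pw == 21 and effects["gs"].n_lw == 21

    def test_single_treatment_trait_skipped_with_warning(self, table):
        sub = table.subset(treatment="PW")
        extra = table.subset(trait="gs")
        df = pd.concat([sub.df[sub.df["trait"] == "LT"], extra.df])
        partial = rw.TraitTable(df)
        with pytest.warns(UserWarning, match="LT"):
            results = rw.effect_sizes_by_trait(partial)
        assert "LT" not in [e.trait for e in results]


class TestWelchT:
    def test_closed_form_equal_variance_case(self):
        r = welch_t([1, 2, 3], [2, 3, 4])
        assert r.statistic == pytest.approx(-np.sqrt(3 / 2), rel=1e-9)
        assert r.df == pytest.approx(4.0)

    def test_identical_groups(self):
        r = welch_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(1.0)

    def test_df_reduces_to_2n_minus_2_for_equal_variances(self):
        # equal n, equal sample variances -> Welch-Satterthwaite df = 2(n-1)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = welch_t(a, a + 10.0)
        assert r.df == pytest.approx(2 * (len(a) - 1))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_matches_scipy_oracle(self, seed):
        from scipy import stats as sps
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 15))
        b = rng.normal(0.5, 2, rng.integers(3, 15))
        ours = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.df == pytest.approx(ref.df, abs=1e-10)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_both_groups_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestAnovaTwoWayBalanced:
    def test_hand_computed_decomposition(self):
        cells = {("PW", "japonica"): [1, 1], ("LW", "japonica"): [3, 3],
                 ("PW", "indica"): [5, 5], ("LW", "indica"): [7, 7]}
        tab = long_table(cells)
        out = rw.anova_two_way_balanced(tab, "y")
        assert out.loc["subspecies", "ss"] == pytest.approx(32.0)
        assert out.loc["treatment", "ss"] == pytest.approx(8.0)
        assert out.loc["treatment:subspecies", "ss"] == pytest.approx(0.0)
        assert out.loc["residual", "ss"] == pytest.approx(0.0)

    def test_all_cells_identical_give_zero_ss(self):
        cells = {(t, s): [2.0, 2.0] for t in ("PW", "LW")
                 for s in ("japonica", "indica")}
        out = rw.anova_two_way_balanced(long_table(cells), "y")
        assert out["ss"].sum() == pytest.approx(0.0)

    def test_unbalanced_design_rejected(self):
        cells = {("PW", "japonica"): [1, 2, 3], ("LW", "japonica"): [3, 3],
                 ("PW", "indica"): [5, 5], ("LW", "indica"): [7, 7]}
        with pytest.raises(UnbalancedDesignError):
            rw.anova_two_way_balanced(long_table(cells), "y")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), r=st.integers(2, 6),
           la=st.integers(2, 3), lb=st.integers(2, 3))
    def test_ss_decomposition_sums_to_total(self, seed, r, la, lb):
        """SS_A + SS_B + SS_AB + SS_error = total SS about the grand mean."""
        rng = np.random.default_rng(seed)
        rows = []
        # trial and genotype are free-form, so both factors can take 3 levels
        for a in range(la):
            for b in range(lb):
                for i in range(r):
                    rows.append([f"G{b}", "japonica", "PW", f"T{a}",
                                 i + 1, "y", 0, rng.normal()])
        tab = rw.TraitTable(pd.DataFrame(
            rows, columns=["genotype", "subspecies", "treatment", "trial",
                           "replicate", "trait", "week", "value"]))
        out = rw.anova_two_way_balanced(tab, "y", factor_a="trial",
                                        factor_b="genotype")
        y = tab.df["value"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert out["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(42)
        cells = {(t, s): rng.normal(size=4).tolist()
                 for t in ("PW", "LW") for s in ("japonica", "indica")}
        tab = long_table(cells)
        ours = rw.anova_two_way_balanced(tab, "y")
        fit = ols("value ~ C(treatment) * C(subspecies)", data=tab.df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert ours.loc["treatment", "ss"] == pytest.approx(
            ref.loc["C(treatment)", "sum_sq"], rel=1e-8)
        assert ours.loc["treatment:subspecies", "F"] == pytest.approx(
            ref.loc["C(treatment):C(subspecies)", "F"], rel=1e-8)
        assert ours.loc["subspecies", "p"] == pytest.approx(
            ref.loc["C(subspecies)", "PR(>F)"], rel=1e-6)


class TestCorrelationMatrix:
    def _table_with(self, columns, n=12):
        rows = []
        for trait, values in columns.items():
            for i, v in enumerate(values):
                rows.append([f"G{i:02d}", "japonica", "PW", "T1", 1, trait, 0, v])
        return rw.TraitTable(pd.DataFrame(
            rows, columns=["genotype", "subspecies", "treatment", "trial",
                           "replicate", "trait", "week", "value"]))

    def test_collinear_traits_flagged_strong(self):
        x = np.arange(10.0)
        tab = self._table_with({"a": x, "b": 2 * x + 1})
        cm = rw.correlation_matrix(tab, by="pooled")
        assert cm.r.loc["a", "b"] == pytest.approx(1.0)
        assert ("a", "b", pytest.approx(1.0)) in cm.strong_pairs

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(1)
        tab = self._table_with({"a": rng.normal(size=1000),
                                "b": rng.normal(size=1000)})
        cm = rw.correlation_matrix(tab, by="pooled")
        assert abs(cm.r.loc["a", "b"]) < 0.1
        assert cm.strong_pairs == []

    def test_constant_trait_undefined_and_excluded(self):
        x = np.arange(6.0)
        cm = rw.correlation_matrix(
            self._table_with({"a": x, "c": np.ones(6)}), by="pooled")
        assert np.isnan(cm.r.loc["a", "c"])
        assert all("c" not in pair[:2] for pair in cm.strong_pairs)

    def test_planted_shared_treatment_response_flagged(self, table):
        """Traits sharing the planted LW response correlate strongly when
        genotype x treatment means are the samples."""
        cm = rw.correlation_matrix(table, traits=["PhiPSII", "FvFm", "gs"],
                                   by="treatment")
        pairs = {frozenset(p[:2]) for p in cm.strong_pairs}
        assert frozenset({"PhiPSII", "FvFm"}) in pairs


class TestPCACorrelation:
    def test_identity_correlation_gives_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        n, p = 2000, 4
        res = rw.pca_correlation(rng.normal(size=(n, p)))
        assert res.eigenvalues == pytest.approx(np.ones(p), abs=0.15)
        assert res.eigenvalues.sum() == pytest.approx(p)

    def test_two_trait_closed_form(self):
        """For 2 standardized traits with correlation r the eigenvalues are
        1 + r and 1 - r."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.normal(size=5000)
        res = rw.pca_correlation(np.c_[x, y])
        r = np.corrcoef(x, y)[0, 1]
        assert res.eigenvalues == pytest.approx([1 + r, 1 - r], rel=1e-10)
        assert res.proportions == pytest.approx(
            [100 * (1 + r) / 2, 100 * (1 - r) / 2], rel=1e-10)

    def test_reconstruction_and_orthonormality(self, table):
        wide = table.mean_matrix()
        res = rw.pca_correlation(wide)
        L = res.loadings.to_numpy()
        lam = res.eigenvalues
        corr = np.corrcoef(
            (wide - wide.mean()) / wide.std(ddof=1), rowvar=False)
        np.testing.assert_allclose(L @ np.diag(lam) @ L.T, corr, atol=1e-8)
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert lam.sum() == pytest.approx(wide.shape[1], rel=1e-10)

    def test_loading_sign_convention(self, table):
        res = rw.pca_from_table(table)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_constant_trait_rejected_by_name(self):
        X = np.c_[np.arange(5.0), np.ones(5)]
        with pytest.raises(DegenerateDataError, match="x2"):
            rw.pca_correlation(X)

    def test_matches_sklearn_oracle(self, table):
        from sklearn.decomposition import PCA
        wide = table.mean_matrix()
        Z = ((wide - wide.mean()) / wide.std(ddof=1)).to_numpy()
        ref = PCA(n_components=3).fit(Z)
        res = rw.pca_correlation(wide)
        np.testing.assert_allclose(
            res.eigenvalues[:3], ref.explained_variance_, rtol=1e-8)
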