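"""Cohort statistics: correlation, aggregation, imputation, GLM, ICC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_spearman
from echotex import reference
from echotex.stats import CollinearityError, DomainError, EMImputer, \
    StandardizedGLM, average_correlations, build_correlation_table, \
    em_impute, encode_glm_predictors, fisher_z, icc_reliability, \
    inverse_fisher_z, little_mcar_test, spearman, standardized_glm, \
    variance_explained


class TestSpearman:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [10, 20, 30], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
    ])
    def test_perfect_monotone(self, x, y, expected):
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_tied_fixture_matches_rank_then_pearson(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        cell = spearman(x, y)
        assert cell.rho == pytest.approx(brute_spearman(x, y), abs=1e-12)
        assert cell.n == 4

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, np.nan, 3.0, 8.0, 10.0]
        cell = spearman(x, y)
        assert cell.n == 3
        assert cell.rho == pytest.approx(brute_spearman([1, 4, 5],
                                                        [2, 8, 10]),
                                         abs=1e-12)

    def test_undefined_cases_marked(self):
        assert not spearman([1, 2], [3, 4]).defined
        assert not spearman([5, 5, 5, 5], [1, 2, 3, 4]).defined

    def test_p_value_matches_t_reference(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        cell = spearman(x, y)
        from scipy import stats as sps
        t = cell.rho * math.sqrt((cell.n - 2) / (1 - cell.rho**2))
        assert cell.p_value == pytest.approx(
            2 * sps.t.sf(abs(t), cell.n - 2), rel=1e-9)

    def test_permutation_method_small_n(self):
        cell = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4],
                        method="permutation")
        assert 0 < cell.p_value <= 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_invariant_under_strict_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)


class TestFisherAggregation:
    def test_round_trip_identity(self):
        for r in (0.0, 0.5, -0.87, 0.999):
            assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r,
                                                                  abs=1e-12)

    def test_known_value(self):
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        assert fisher_z(0.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            fisher_z(1.0)
        with pytest.raises(DomainError):
            average_correlations([])

    def test_fixed_point_for_identical_inputs(self):
        agg = average_correlations([0.37, 0.37, 0.37])
        assert agg.r_back == pytest.approx(0.37, abs=1e-12)

    @pytest.mark.parametrize("feature", reference.FEATURE_NAMES)
    def test_published_average_column(self, feature):
        """Each published row back-averages to its printed coefficient."""
        rhos = [reference.REFERENCE_RHO[feature][t]
                for t in reference.TEST_NAMES]
        agg = average_correlations(rhos)
        assert agg.r_rounded == pytest.approx(
            reference.REFERENCE_AVERAGE_R[feature], abs=1e-12)

    def test_magnitude_bounded_by_largest_input(self, rng):
        rhos = rng.uniform(-0.6, 0.6, size=7)
        agg = average_correlations(rhos)
        assert abs(agg.r_back) <= max(abs(r) for r in rhos) + 1e-12


class TestEMImputation:
    def test_complete_data_returns_ml_moments(self, rng):
        X = rng.normal(size=(200, 3)) @ np.array([[1, .5, 0],
                                                  [0, 1, .3],
                                                  [0, 0, 1.0]])
        filled, imp = em_impute(X)
        assert np.allclose(filled, X)
        assert np.allclose(imp.mean_, X.mean(axis=0), atol=1e-10)
        assert np.allclose(imp.covariance_, np.cov(X.T, bias=True),
                           atol=1e-8)

    def test_bivariate_conditional_mean_closed_form(self, rng):
        """One masked value lands on mu1 + rho*(s1/s2)*(x2 - mu2)."""
        rho, n = 0.8, 4000
        cov = np.array([[1.0, rho], [rho, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=n)
        Xm = X.copy()
        Xm[0, 0] = np.nan
        filled, imp = em_impute(Xm, tol=1e-10)
        mu, S = imp.mean_, imp.covariance_
        expected = mu[0] + S[0, 1] / S[1, 1] * (X[0, 1] - mu[1])
        assert filled[0, 0] == pytest.approx(expected, abs=1e-8)
        # and the fitted moments are close to truth at this n
        assert abs(S[0, 1] - rho) < 0.05

    def test_mvn_moment_recovery_under_mcar(self, rng):
        """10% MCAR at n=2000: recovered means within 3 SE of truth."""
        mu_true = np.array([1.0, -2.0, 0.5, 3.0])
        A = rng.normal(size=(4, 4)) * 0.4 + np.eye(4)
        cov = A @ A.T
        n = 2000
        X = rng.multivariate_normal(mu_true, cov, size=n)
        Xm = X.copy()
        Xm[rng.random(size=X.shape) < 0.10] = np.nan
        _, imp = em_impute(Xm)
        se = np.sqrt(np.diag(cov) / (~np.isnan(Xm)).sum(axis=0))
        assert np.all(np.abs(imp.mean_ - mu_true) < 3 * se)

    def test_sklearn_transform_on_new_rows(self, rng):
        X = rng.multivariate_normal([0, 0], [[1, .9], [.9, 1]], size=500)
        imp = EMImputer().fit(X)
        new = np.array([[np.nan, 2.0]])
        filled = imp.transform(new)
        assert filled[0, 0] == pytest.approx(
            imp.mean_[0] + imp.covariance_[0, 1] / imp.covariance_[1, 1]
            * (2.0 - imp.mean_[1]), abs=1e-10)

    def test_variable_observed_once_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan], [3.0, 5.0]])
        with pytest.raises(ValueError, match="fewer"):
            EMImputer().fit(X)


class TestLittleMCAR:
    def test_complete_data_statistic_zero(self, rng):
        X = rng.normal(size=(50, 4))
        res = little_mcar_test(X)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.df == 0
        assert res.p_value == 1.0

    def test_null_pvalues_uniform_under_mcar(self):
        """KS check of p-value calibration over MCAR replications."""
        rng = np.random.default_rng(42)
        pvals = []
        cov = np.array([[1, .4, .2], [.4, 1, .3], [.2, .3, 1.0]])
        for _ in range(150):
            X = rng.multivariate_normal([0, 1, -1], cov, size=250)
            X[rng.random(X.shape) < 0.10] = np.nan
            pvals.append(little_mcar_test(X, tol=1e-5).p_value)
        from scipy import stats as sps
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_strong_mar(self):
        rng = np.random.default_rng(43)
        rejections = 0
        reps = 30
        for _ in range(reps):
            X = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]],
                                        size=400)
            # second variable missing whenever the first is large
            mask = X[:, 0] > 0.5
            X[mask, 1] = np.nan
            if little_mcar_test(X, tol=1e-5).p_value < 0.05:
                rejections += 1
        assert rejections / reps > 0.5


class TestStandardizedGLM:
    def _predictors(self, rng, n):
        return pd.DataFrame({
            "age": rng.normal(65, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "egfr": rng.normal(34, 15, n),
            "hb": rng.normal(126, 16, n),
            "albumin": rng.normal(42, 2.5, n),
            "bmi": rng.normal(29, 6, n),
        })

    def test_recovers_known_standardized_effect(self, rng):
        n = 2000
        X = self._predictors(rng, n)
        zhb = (X["hb"] - X["hb"].mean()) / X["hb"].std(ddof=1)
        y = 0.5 * zhb + rng.normal(size=n)
        model = StandardizedGLM().fit(X, y)
        beta = dict(zip(model.feature_names_in_, model.coef_))
        assert beta["hb"] == pytest.approx(0.5 / math.sqrt(1.25), abs=0.05)
        for other in ("age", "sex", "egfr", "albumin", "bmi"):
            assert abs(beta[other]) < 0.06

    def test_exact_fit_limit(self, rng):
        X = self._predictors(rng, 100)
        y = X["age"].to_numpy()
        model = StandardizedGLM().fit(X, y)
        beta = dict(zip(model.feature_names_in_, model.coef_))
        assert beta["age"] == pytest.approx(1.0, abs=1e-8)
        assert dict(zip(model.feature_names_in_,
                        model.pvalues_))["age"] < 1e-30

    def test_row_permutation_invariance(self, rng):
        X = self._predictors(rng, 60)
        y = rng.normal(size=60)
        perm = rng.permutation(60)
        b1 = StandardizedGLM().fit(X, y).coef_
        b2 = StandardizedGLM().fit(X.iloc[perm], y[perm]).coef_
        assert np.allclose(b1, b2, atol=1e-10)

    def test_collinear_design_names_columns(self, rng):
        X = self._predictors(rng, 50)
        X["hb2"] = X["hb"] * 2.0
        with pytest.raises(CollinearityError, match="hb"):
            StandardizedGLM().fit(X, rng.normal(size=50))

    def test_p_consistent_with_t_distribution(self, rng):
        from scipy import stats as sps
        X = self._predictors(rng, 80)
        y = rng.normal(size=80)
        model = StandardizedGLM().fit(X, y)
        for t, p in zip(model.tvalues_, model.pvalues_):
            assert p == pytest.approx(2 * sps.t.sf(abs(t),
                                                   model.df_resid_),
                                      rel=1e-9)

    def test_categorical_coding_helper(self):
        df = pd.DataFrame({"age": [60.0, 70.0], "sex": ["male", "female"],
                           "ethnicity": ["white", "south_asian"],
                           "egfr": [30.0, 40.0], "hb": [120.0, 130.0],
                           "albumin": [40.0, 44.0], "bmi": [25.0, 30.0]})
        enc = encode_glm_predictors(df)
        assert enc["sex"].tolist() == [1.0, 0.0]
        assert enc["ethnicity"].tolist() == [1.0, 0.0]


class TestVarianceExplained:
    def test_exact_linear_combination_gives_r2_one(self, rng):
        F = pd.DataFrame(rng.normal(size=(100, 5)),
                         columns=list(reference.FEATURE_NAMES))
        y = F @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        assert variance_explained(y, F) == pytest.approx(1.0, abs=1e-10)

    def test_null_r2_small_at_large_n(self, rng):
        n = 2000
        F = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=list(reference.FEATURE_NAMES))
        y = rng.normal(size=n)
        r2 = variance_explained(y, F)
        assert r2 < 5 * 5 / (n - 1)  # ~E[R2] = k/(n-1) under the null

    def test_duplicate_feature_aliased_not_fatal(self, rng):
        F = pd.DataFrame(rng.normal(size=(50, 5)),
                         columns=list(reference.FEATURE_NAMES))
        y = rng.normal(size=50)
        base = variance_explained(y, F)
        F6 = F.copy()
        F6["dup"] = F6["asm"]
        with pytest.warns(RuntimeWarning, match="aliased"):
            assert variance_explained(y, F6) == pytest.approx(base,
                                                              abs=1e-10)


class TestICC:
    def test_identical_measures(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = icc_reliability(x, x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.diff_p == 1.0

    def test_constant_shift_absolute_vs_consistency(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = icc_reliability(x, x + 1.0)
        assert res.icc < 1.0                      # absolute agreement drops
        assert res.icc_consistency == pytest.approx(1.0, abs=1e-12)

    def test_matches_pingouin_oracle(self, rng):
        m1 = rng.normal(size=25)
        m2 = 0.8 * m1 + 0.3 + rng.normal(scale=0.4, size=25)
        res = icc_reliability(m1, m2)
        import pingouin as pg
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile(["a", "b"], 25),
            "score": np.column_stack([m1, m2]).ravel()})
        icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        assert res.icc == pytest.approx(icc.loc["ICC(A,1)", "ICC"],
                                        abs=1e-6)
        assert res.icc_consistency == pytest.approx(
            icc.loc["ICC(C,1)", "ICC"], abs=1e-6)

    def test_independent_noise_icc_near_zero(self, rng):
        m1 = rng.normal(size=200)
        m2 = rng.normal(size=200)
        assert abs(icc_reliability(m1, m2).icc) < 0.15

    def test_zero_between_subject_variance_undefined(self):
        res = icc_reliability([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert not res.defined


class TestCorrelationTable:
    def _cohort(self, rng, n=80):
        df = pd.DataFrame(rng.normal(size=(n, 10)),
                          columns=list(reference.FEATURE_NAMES)
                          + list(reference.TEST_NAMES))
        return df

    def test_perfect_anticorrelation_cell(self, rng):
        df = self._cohort(rng)
        df["iswt"] = -df["entropy"].rank()
        tab = build_correlation_table(df)
        assert tab.cells[("entropy", "iswt")].rho == pytest.approx(
            -1.0, abs=1e-12)

    def test_published_grid_reproduces_average_column(self):
        """Injecting the published rho grid reproduces the printed averages."""
        aggs = {f: average_correlations(
            [reference.REFERENCE_RHO[f][t] for t in reference.TEST_NAMES])
            for f in reference.FEATURE_NAMES}
        got = {f: a.r_rounded for f, a in aggs.items()}
        assert got == {"asm": 0.130, "entropy": -0.177, "idm": 0.167,
                       "correlation": 0.150, "contrast": -0.147}
        best = max(aggs, key=lambda f: abs(aggs[f].r_back))
        assert best == "entropy"

    def test_all_missing_column_skipped_with_warning(self, rng):
        df = self._cohort(rng)
        df["tuag"] = np.nan
        with pytest.warns(RuntimeWarning, match="tuag"):
            tab = build_correlation_table(df)
        assert ("entropy", "tuag") not in tab.cells
        assert len(tab.aggregates["entropy"].z_values) == 4

    def test_aggregate_sign_and_bound(self, rng):
        df = self._cohort(rng, n=200)
        tab = build_correlation_table(df)
        for f, agg in tab.aggregates.items():
            inputs = [tab.cells[(f, t)].rho for t in tab.tests]
            assert abs(agg.r_back) <= max(abs(r) for r in inputs) + 1e-12
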