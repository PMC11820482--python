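"""Descriptives, screens, imputation and the three-model cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wbq.analysis import (
    MODEL1_GROUPS,
    assess_mar,
    assess_normality,
    build_design,
    compare_by_gender,
    diagnostics,
    fit_models,
    impute_chained,
    pooled_ols,
    univariate_screen,
)
from wbq.stats import design_matrix, linear_fit


class TestNormality:
    def test_normal_generator_mostly_passes(self):
        rng = np.random.default_rng(0)
        verdicts = [assess_normality(rng.normal(size=200)).normal
                    for _ in range(100)]
        assert np.mean(verdicts) >= 0.90

    def test_heavy_tails_mostly_fail(self):
        rng = np.random.default_rng(1)
        verdicts = [assess_normality(rng.standard_t(2, size=200)).normal
                    for _ in range(100)]
        assert np.mean(verdicts) <= 0.10

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            assess_normality([1.0, 2.0])

    def test_constant_vector(self):
        with pytest.raises(ValueError, match="constant"):
            assess_normality([3.0] * 50)


class TestCompareByGender:
    @staticmethod
    def _frame(male_vals, female_vals):
        return pd.DataFrame({
            "gender": ["male"] * len(male_vals) + ["female"] * len(female_vals),
            "v": list(male_vals) + list(female_vals),
        })

    def test_identical_binary_proportions_null(self):
        df = self._frame(["yes"] * 30 + ["no"] * 70, ["yes"] * 30 + ["no"] * 70)
        res = compare_by_gender(df, "v")
        assert res.test == "chi-square"
        assert res.pvalue > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 40
        for _ in range(reps):
            df = self._frame(rng.normal(1.5, 1, 100), rng.normal(0, 1, 100))
            if compare_by_gender(df, "v").pvalue < 0.001:
                hits += 1
        assert hits / reps >= 0.95

    def test_contingency_table_against_closed_form(self):
        df = self._frame(["a"] * 30 + ["b"] * 70, ["a"] * 70 + ["b"] * 30)
        res = compare_by_gender(df, "v")
        # hand chi-square with Yates continuity correction on ((30,70),(70,30))
        obs = np.array([[30, 70], [70, 30]])
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((np.abs(obs - expected) - 0.5) ** 2 / expected).sum()
        assert res.pvalue < 1e-6
        assert res.statistic == pytest.approx(stat, rel=1e-12)

    def test_skewed_data_uses_wilcoxon(self):
        rng = np.random.default_rng(3)
        df = self._frame(rng.lognormal(1, 1, 120), rng.lognormal(1.0, 1, 120))
        res = compare_by_gender(df, "v")
        assert res.test == "Wilcoxon"
        assert "[" in next(iter(res.summaries.values()))  # median [Q1, Q3]

    def test_empty_group_raises(self):
        df = pd.DataFrame({"gender": ["male"] * 5, "v": range(5)})
        with pytest.raises(ValueError):
            compare_by_gender(df, "v")


class TestUnivariateScreen:
    def test_noiseless_limit_recovers_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "balance": 2 * x + 1e-10 * rng.normal(size=50)})
        res = univariate_screen(df, ["x"], groups={"x": ["x"]})
        fit = res[0].fit
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-6)
        assert fit.pvalues[1] < 1e-12

    def test_constant_predictor_skipped_with_log(self):
        df = pd.DataFrame({"x": np.ones(30),
                           "balance": np.random.default_rng(5).normal(size=30)})
        log: list[str] = []
        res = univariate_screen(df, ["x"], groups={"x": ["x"]}, log=log)
        assert res == [] and any("x" in entry for entry in log)

    def test_matches_normal_equations_oracle(self, scored_small):
        design = build_design(scored_small)
        results = univariate_screen(design)
        y = design["balance"].to_numpy(float)
        for r in results:
            cols = r.fit.terms[1:]
            sub = design[cols + ["balance"]].dropna()
            X = design_matrix(sub, cols)
            beta = np.linalg.solve(X.T @ X, X.T @ sub["balance"].to_numpy(float))
            np.testing.assert_allclose(r.fit.beta, beta, atol=1e-8)

    def test_type_one_error_near_nominal(self):
        # fuller 1000-replicate version lives in the acceptance suite
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({"x": rng.normal(size=50),
                               "balance": rng.normal(size=50)})
            fit = univariate_screen(df, ["x"], groups={"x": ["x"]})[0].fit
            rejections += fit.pvalues[1] < 0.05
        assert abs(rejections / reps - 0.05) <= 0.04


class TestAssessMar:
    def test_no_missing_cells_gives_empty_report(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [4.0, 5, 6]})
        assert assess_mar(df).empty

    def test_mcar_flags_near_nominal_rate(self):
        rng = np.random.default_rng(7)
        flags = []
        for _ in range(120):
            df = pd.DataFrame({"age": rng.normal(40, 10, 300),
                               "v": rng.normal(size=300)})
            df.loc[rng.random(300) < 0.15, "v"] = np.nan
            rep = assess_mar(df, covariates=["age"])
            flags.append(rep.screens["v"].loc["age", "p"] < 0.05)
        assert abs(np.mean(flags) - 0.05) <= 0.05

    def test_mar_on_age_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 20
        for _ in range(reps):
            age = rng.normal(40, 10, 500)
            z = (age - age.mean()) / age.std()
            miss = rng.random(500) < 1 / (1 + np.exp(-(-2 + 1.2 * z)))
            df = pd.DataFrame({"age": age, "v": rng.normal(size=500)})
            df.loc[miss, "v"] = np.nan
            rep = assess_mar(df, covariates=["age"])
            hits += rep.screens["v"].loc["age", "p"] < 0.05
            assert rep.systematic["v"] in (True, False)
        assert hits / reps >= 0.90

    def test_separation_reported_not_raised(self):
        # covariate perfectly predicts missingness
        df = pd.DataFrame({"x": np.repeat([0.0, 1.0], 30),
                           "v": np.r_[np.full(30, np.nan), np.ones(30)]})
        rep = assess_mar(df, covariates=["x"])
        row = rep.screens["v"].loc["x"]
        assert not row["estimable"] or abs(row["coef"]) < 15


class TestChainedImputation:
    @staticmethod
    def _table_with_missing(n=200, seed=9, rate=0.15):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        b = (rng.random(n) < 0.4).astype(float)
        y = 1.5 * x + 2.0 * b + rng.normal(0, 0.8, n)
        df = pd.DataFrame({"x": x, "b": b, "y": y})
        df.loc[rng.random(n) < rate, "x"] = np.nan
        df.loc[rng.random(n) < rate, "b"] = np.nan
        return df

    def test_identity_on_complete_data(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [0.0, 1, 0, 1]})
        imps = impute_chained(df, m=4, seed=1)
        for comp in imps.completions:
            pd.testing.assert_frame_equal(comp, df.astype(float))

    def test_determinism_under_seed(self):
        df = self._table_with_missing()
        a = impute_chained(df, m=3, seed=11)
        b = impute_chained(df, m=3, seed=11)
        for ca, cb in zip(a.completions, b.completions):
            pd.testing.assert_frame_equal(ca, cb)

    def test_different_seed_differs(self):
        df = self._table_with_missing()
        a = impute_chained(df, m=1, seed=11)
        b = impute_chained(df, m=1, seed=12)
        assert not a.completions[0].equals(b.completions[0])

    def test_observed_cells_untouched_and_no_missing_left(self):
        df = self._table_with_missing()
        imps = impute_chained(df, m=3, seed=13)
        obs = df.notna()
        for comp in imps.completions:
            assert not comp.isna().any().any()
            pd.testing.assert_frame_equal(comp.where(obs), df.where(obs))
        assert imps.methods == {"x": "linear", "b": "logistic"}

    def test_fully_missing_variable_is_named(self):
        df = pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="x"):
            impute_chained(df, m=2, seed=1)

    def test_pooled_slope_recovers_truth_under_mcar(self):
        rng = np.random.default_rng(14)
        slopes = []
        for _ in range(30):
            n = 400
            x = rng.normal(size=n)
            y = 2.0 * x + rng.normal(0, 1, n)
            df = pd.DataFrame({"x": x, "y": y})
            df.loc[rng.random(n) < 0.2, "x"] = np.nan
            imps = impute_chained(df, m=5, seed=int(rng.integers(2 ** 31)))
            slopes.append(pooled_ols(imps.completions, ["x"], "y").coef("x"))
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) <= 3 * mc_se


class TestModelCascade:
    def test_m1_with_single_complete_imputation_equals_ols(self, scored_small):
        design = build_design(scored_small)
        cols = [c for g in MODEL1_GROUPS.values() for c in g]
        imps = impute_chained(design[cols + ["balance"]], m=1, seed=2)
        models = fit_models(imps)
        single = linear_fit(design_matrix(design, cols),
                            design["balance"].to_numpy(float))
        np.testing.assert_allclose(models.model1.beta, single.beta, atol=1e-10)
        np.testing.assert_allclose(models.model1.se, single.se, atol=1e-10)

    def test_nesting_of_term_sets(self, scored_small):
        design = build_design(scored_small)
        cols = [c for g in MODEL1_GROUPS.values() for c in g]
        imps = impute_chained(design[cols + ["balance"]], m=2, seed=3)
        models = fit_models(imps)
        assert set(models.terms3) <= set(models.terms2) <= set(models.terms1)

    def test_selection_keeps_strong_planted_terms(self):
        rng = np.random.default_rng(15)
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 500
            X = rng.standard_normal((n, 12))
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(12)])
            df["balance"] = (3.0 * X[:, 0] - 2.5 * X[:, 5] + 2.0 * X[:, 9]
                             + rng.standard_normal(n))
            groups = {c: [c] for c in df.columns if c != "balance"}
            imps = impute_chained(df, m=1, seed=int(rng.integers(2 ** 31)))
            models = fit_models(imps, groups=groups)
            hits += {"x0", "x5", "x9"} <= set(models.terms2)
        assert hits / reps >= 0.90


class TestDiagnostics:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(16)
        Q, _ = np.linalg.qr(rng.standard_normal((80, 4)))
        df = pd.DataFrame(Q[:, :3], columns=["a", "b", "c"])
        df["balance"] = rng.standard_normal(80)
        rep = diagnostics(df, ["a", "b", "c"])
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=0.1)

    def test_duplicated_predictor_flagged(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"a": rng.normal(size=60)})
        df["a_copy"] = df["a"]
        df["balance"] = rng.normal(size=60)
        rep = diagnostics(df, ["a", "a_copy"])
        assert set(rep.vif_flags) == {"a", "a_copy"}

    def test_vif_matches_statsmodels_oracle(self, scored_small):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        design = build_design(scored_small)
        cols = ["age", "bmi", "education_years", "work_hours_week",
                "gender_male"]
        sub = design[cols + ["balance"]].dropna()
        rep = diagnostics(sub, cols)
        X = design_matrix(sub, cols)
        for i, c in enumerate(cols):
            ref = variance_inflation_factor(X, i + 1)
            assert rep.vif[c] == pytest.approx(ref, abs=1e-8)

    def test_residual_checks_present(self, scored_small):
        design = build_design(scored_small)
        rep = diagnostics(design.dropna(), ["age", "education_years"])
        assert rep.residual_normality is not None
        assert 0 <= rep.heteroscedasticity["lm_p"] <= 1
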