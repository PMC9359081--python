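import numpy as np
import pandas as pd
import pytest

from nlnc import (
    ExpressionMatrix,
    SignatureModel,
    SimulationConfig,
    compute_risk_score,
    dichotomize,
    fit_lasso_cox_cv,
    multivariate_cox_refit,
    simulate_cohort,
    univariate_cox_screen,
    zscore_normalize,
)
from nlnc.signature import apply_normalization


def _expr(values: dict, biotype="lncRNA"):
    df = pd.DataFrame(values).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, pd.Series(biotype, index=df.index))


class TestZscore:
    def test_definition(self):
        z, rec = zscore_normalize(_expr({"f": [1.0, 2.0, 3.0]}))
        row = z.values.loc["f"]
        assert row.mean() == pytest.approx(0.0)
        assert row.std(ddof=0) == pytest.approx(1.0)
        assert rec.loc["f", "mean"] == pytest.approx(2.0)

    def test_constant_feature_becomes_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z, rec = zscore_normalize(_expr({"f": [5.0, 5.0, 5.0]}))
        assert (z.values.loc["f"] == 0).all()
        assert rec.loc["f", "sd"] == 0

    def test_stored_constants_round_trip(self):
        expr = _expr({"a": [1.0, 4.0, 7.0], "b": [2.0, 2.0, 8.0]})
        z, rec = zscore_normalize(expr)
        again = apply_normalization(expr.values, rec)
        pd.testing.assert_frame_equal(again, z.values)


def _planted_survival(n, betas, seed, censor_frac=0.3):
    """Small PH cohort over independent standard-normal features."""
    rng = np.random.default_rng(seed)
    p = len(betas)
    X = rng.normal(size=(p, n))
    lp = betas @ X
    T = 3.8 * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1 / 1.5)
    C = np.quantile(T, 1 - censor_frac) * rng.uniform(0.5, 1.5, size=n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    genes = [f"f{i}" for i in range(p)]
    expr = ExpressionMatrix(
        pd.DataFrame(X, index=genes, columns=[f"S{i}" for i in range(n)]),
        pd.Series("lncRNA", index=genes))
    clin = pd.DataFrame({"time": t, "event": e}, index=expr.sample_ids)
    return expr, clin


class TestUnivariateScreen:
    def test_strong_feature_is_candidate(self):
        expr, clin = _planted_survival(500, np.array([0.8, 0.0]), seed=1)
        cands, table = univariate_cox_screen([(expr, clin)])
        assert "f0" in cands
        assert set(table.columns) == {"feature_id", "cohort_id", "beta", "hr", "p"}
        assert np.allclose(table["hr"], np.exp(table["beta"]))

    def test_opposite_direction_rejected_across_cohorts(self):
        a = _planted_survival(400, np.array([0.8]), seed=2)
        b = _planted_survival(400, np.array([-0.8]), seed=3)
        cands, table = univariate_cox_screen([a, b])
        assert (table["p"] < 0.15).all()  # significant everywhere...
        assert cands == []                # ...but directions disagree

    def test_single_cohort_reduces_to_p_filter(self):
        expr, clin = _planted_survival(300, np.array([0.7, 0.0, 0.0]), seed=4)
        cands, table = univariate_cox_screen([(expr, clin)], p_threshold=0.15)
        expected = set(table.loc[table["p"] < 0.15, "feature_id"])
        assert set(cands) == expected


class TestLassoCox:
    def test_lambda_max_gives_empty_model(self):
        expr, clin = _planted_survival(200, np.array([0.8, -0.6, 0.0, 0.0]), seed=5)
        cv = fit_lasso_cox_cv(expr.values.T, clin, n_folds=5, seed=0)
        assert np.all(cv.coef_path.iloc[:, 0].to_numpy() == 0.0)

    def test_shrinkage_relative_to_unpenalized_refit(self):
        expr, clin = _planted_survival(400, np.array([0.8, -0.8, 0.6, 0.0, 0.0]), seed=6)
        X = expr.values.T
        cv = fit_lasso_cox_cv(X, clin, n_folds=5, seed=1)
        sel = cv.model.feature_ids
        mv, _ = multivariate_cox_refit(X[sel], clin)
        for f, c in zip(sel, cv.model.coefficients):
            assert abs(c) <= abs(mv.loc[f, "beta"]) + 1e-6

    def test_full_path_fit_is_sample_order_invariant(self):
        expr, clin = _planted_survival(200, np.array([0.8, -0.6]), seed=7)
        X = expr.values.T
        perm = np.random.default_rng(0).permutation(len(X))
        cv1 = fit_lasso_cox_cv(X, clin, n_folds=4, seed=2)
        cv2 = fit_lasso_cox_cv(X.iloc[perm], clin.iloc[perm], n_folds=4, seed=2)
        pd.testing.assert_frame_equal(cv1.coef_path, cv2.coef_path, atol=1e-8)


class TestMultivariateRefit:
    def test_single_feature_equals_univariate(self):
        expr, clin = _planted_survival(300, np.array([0.7]), seed=8)
        X = expr.values.T
        mv, _ = multivariate_cox_refit(X, clin)
        _, uni_table = univariate_cox_screen([(expr, clin)])
        assert mv.loc["f0", "beta"] == pytest.approx(uni_table["beta"].iloc[0], abs=1e-8)

    def test_collinear_features_rejected(self):
        expr, clin = _planted_survival(200, np.array([0.7]), seed=9)
        X = expr.values.T
        X["dup"] = X["f0"]
        with pytest.raises(ValueError, match="ollinear"):
            multivariate_cox_refit(X, clin)

    def test_null_feature_dropped_planted_kept(self):
        expr, clin = _planted_survival(600, np.array([0.8, 0.0]), seed=10)
        _, retained = multivariate_cox_refit(expr.values.T, clin, alpha=0.05)
        assert "f0" in retained and "f1" not in retained


class TestRiskScore:
    @staticmethod
    def _model():
        norm = pd.DataFrame({"mean": [0.0, 0.0], "sd": [1.0, 1.0]}, index=["a", "b"])
        return SignatureModel(["a", "b"], [2.0, -1.0], 0.1, norm)

    def test_linearity_and_arithmetic(self):
        m = self._model()
        expr = ExpressionMatrix(
            pd.DataFrame({"S1": [1.5, 0.0], "S2": [0.0, 0.0]}, index=["a", "b"]),
            pd.Series("lncRNA", index=["a", "b"]))
        s = compute_risk_score(expr, m)
        assert s["S1"] == pytest.approx(3.0)
        assert s["S2"] == pytest.approx(0.0)
        # additivity over disjoint feature subsets
        ma = SignatureModel(["a"], [2.0], 0.1, m.normalization.loc[["a"]])
        mb = SignatureModel(["b"], [-1.0], 0.1, m.normalization.loc[["b"]])
        sa, sb = compute_risk_score(expr, ma), compute_risk_score(expr, mb)
        pd.testing.assert_series_equal(s, sa + sb, check_names=False)

    def test_missing_feature_is_an_error(self):
        m = self._model()
        expr = ExpressionMatrix(pd.DataFrame({"S1": [1.0]}, index=["a"]),
                                pd.Series("lncRNA", index=["a"]))
        with pytest.raises(ValueError, match="b"):
            compute_risk_score(expr, m)

    def test_invariant_to_constant_shift_of_raw_expression(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(2, 30)), index=["a", "b"],
                            columns=[f"S{i}" for i in range(30)])
        expr = ExpressionMatrix(vals, pd.Series("lncRNA", index=["a", "b"]))
        shifted = ExpressionMatrix(vals.copy(), expr.biotype)
        shifted.values.loc["a"] += 100.0
        m = self._model()
        s1 = compute_risk_score(expr, m, renormalize=True)
        s2 = compute_risk_score(shifted, m, renormalize=True)
        pd.testing.assert_series_equal(s1, s2)


class TestDichotomize:
    def test_median_split_even_n(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        table, cutoff = dichotomize(scores)
        assert cutoff == pytest.approx(2.5)
        assert set(table.loc[table.group == "high"].index) == {"c", "d"}

    def test_large_min_group_fraction_forces_median(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        t = rng.exponential(3, size=40) + 0.1
        clin = pd.DataFrame({"time": t, "event": np.ones(40, int)}, index=scores.index)
        _, c_opt = dichotomize(scores, clin, method="optimal_logrank",
                               min_group_fraction=0.5)
        _, c_med = dichotomize(scores, method="median")
        assert c_opt == pytest.approx(c_med, abs=np.diff(np.sort(scores))[19] + 1e-9)

    def test_optimal_logrank_recovers_planted_step(self):
        rng = np.random.default_rng(2)
        n = 300
        scores = pd.Series(np.sort(rng.uniform(0, 10, size=n)),
                           index=[f"s{i}" for i in range(n)])
        hazard = np.where(scores > 6.0, 4.0, 1.0)  # step at score 6
        t = rng.exponential(1.0 / hazard) + 1e-3
        clin = pd.DataFrame({"time": t, "event": np.ones(n, int)}, index=scores.index)
        _, cutoff = dichotomize(scores, clin, method="optimal_logrank")
        assert 5.5 < cutoff < 6.5

    def test_constant_scores_rejected(self):
        scores = pd.Series([1.0] * 5, index=list("abcde"))
        with pytest.raises(ValueError, match="identical"):
            dichotomize(scores)


def test_lasso_recovery_on_generator_cohort():
    """Planted prognostic lncRNAs are selected with correct signs."""
    cfg = SimulationConfig(n_samples=600, n_mrna=30, n_lncrna=24, notch_set_size=10,
                           n_driver_lnc=6, n_prognostic_lnc=6, driver_effect=0.0,
                           beta=[0.8, -0.8, 0.6, -0.6, 0.5, -0.5],
                           censoring_rate=0.3, seed=77)
    co = simulate_cohort(cfg)
    z, _ = zscore_normalize(co.expression.subset_genes(co.expression.lncrna_ids))
    cv = fit_lasso_cox_cv(z.values.T, co.clinical, n_folds=10, seed=77)
    sel = dict(zip(cv.model.feature_ids, cv.model.coefficients))
    planted = co.truth.prognostic_betas
    hits = set(sel) & set(planted)
    assert len(hits) >= 5
    for g in hits:
        assert np.sign(sel[g]) == np.sign(planted[g])
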