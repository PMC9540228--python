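"""Tests for the group-level regression and correlation stage."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import statsmodels.api as sm
from scipy import stats

from birdwatch.group import (aggregate_ravlt, hierarchical_regression,
                             partial_correlation, sample_covariates,
                             stepwise_regression)


class TestRavlt:
    def test_learning_total_sums_first_five_trials(self):
        scores = aggregate_ravlt([5, 7, 9, 11, 13, 12, 11], [0, 0, 0, 0, 0])
        assert scores.learning_total == 45

    def test_interference_and_delay_costs(self):
        scores = aggregate_ravlt([5, 7, 9, 11, 12, 12, 10], [0, 0, 0, 0, 0])
        assert scores.interference_cost == 0
        assert scores.delay_cost == 2

    def test_recognition_errors_sum_categories(self):
        scores = aggregate_ravlt([1, 2, 3, 4, 5, 5, 5], [1, 0, 2, 0, 1])
        assert scores.recognition_errors == 4

    def test_missing_trial_flags_dependent_outputs(self):
        scores = aggregate_ravlt([5, 7, None, 11, 13, 12, 11], [0, 0, 0, 0, 0])
        assert "learning_total" in scores.missing
        assert np.isnan(scores.learning_total)
        assert scores.interference_cost == 1  # A5 - A6 unaffected


class TestStepwise:
    def test_perfect_predictor_selected_alone(self, rng):
        n = 40
        x1 = rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "x2": rng.normal(size=n)})
        rep = stepwise_regression(pd.Series(2.0 * x1), X)
        assert list(rep.terms.index) == ["const", "x1"]
        assert rep.r2 == pytest.approx(1.0)

    def test_null_model_reported_when_nothing_enters(self, rng):
        n = 40
        X = pd.DataFrame({"x1": rng.normal(size=n)})
        # y orthogonal to x1 by construction
        y = pd.Series(rng.normal(size=n))
        y -= np.polyval(np.polyfit(X["x1"], y, 1), X["x1"])
        rep = stepwise_regression(y, X)
        assert rep.empty

    def test_family_wise_spurious_entry_rate(self):
        # independent y: >= 1 spurious entry in at most 1-(1-.05)^5 + tol
        rng = np.random.default_rng(30)
        reps, spurious = 400, 0
        for _ in range(reps):
            n = 40
            X = pd.DataFrame(rng.normal(size=(n, 5)),
                             columns=[f"x{i}" for i in range(5)])
            rep = stepwise_regression(pd.Series(rng.normal(size=n)), X)
            spurious += not rep.empty
        assert spurious / reps <= (1 - 0.95 ** 5) + 0.06

    def test_power_for_two_strong_orthogonalish_effects(self):
        rng = np.random.default_rng(31)
        both = 0
        for _ in range(200):
            n = 60
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            y = pd.Series(x1 + x2 + rng.normal(0, 0.5, n))
            X = pd.DataFrame({"x1": x1, "x2": x2,
                              "noise": rng.normal(size=n)})
            rep = stepwise_regression(y, X)
            both += {"x1", "x2"} <= set(rep.terms.index)
        assert both >= 0.95 * 200

    def test_invariant_to_candidate_column_order(self, rng):
        n = 50
        x1, x2, x3 = rng.normal(size=(3, n))
        y = pd.Series(1.5 * x1 - 1.0 * x3 + rng.normal(0, 0.5, n))
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        a = stepwise_regression(y, X)
        b = stepwise_regression(y, X[["x3", "x2", "x1"]])
        assert set(a.terms.index) == set(b.terms.index)

    def test_too_few_cases_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        X.columns = [f"x{i}" for i in range(4)]
        with pytest.raises(ValueError):
            stepwise_regression(pd.Series(rng.normal(size=5)), X)


class TestHierarchical:
    def test_empty_step1_reduces_to_multiple_regression(self, rng):
        n = 50
        X2 = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = pd.Series(X2["a"] - 2 * X2["b"] + rng.normal(0, 0.3, n))
        h = hierarchical_regression(y, X2.iloc[:, :0], X2)
        direct = sm.OLS(y, sm.add_constant(X2)).fit()
        assert h.step2.r2 == pytest.approx(direct.rsquared)
        assert h.delta_r2 == pytest.approx(direct.rsquared)
        np.testing.assert_allclose(h.step2.terms["beta"], direct.params)

    def test_step1_fit_matches_plain_least_squares(self, rng):
        n = 40
        X1 = pd.DataFrame({"age": rng.normal(70, 4, n)})
        X2 = pd.DataFrame({"vol": rng.normal(size=n)})
        y = pd.Series(rng.normal(size=n))
        h = hierarchical_regression(y, X1, X2)
        direct = sm.OLS(y, sm.add_constant(X1)).fit()
        assert h.step1.r2 == pytest.approx(direct.rsquared)

    def test_null_step2_has_calibrated_f_change(self):
        # step-2 predictors independent of y: Delta R^2 small, p ~ uniform
        rng = np.random.default_rng(32)
        deltas, pvals = [], []
        for _ in range(300):
            n = 50
            X1 = pd.DataFrame({"c": rng.normal(size=n)})
            X2 = pd.DataFrame({"z": rng.normal(size=n)})
            y = pd.Series(X1["c"] + rng.normal(size=n))
            h = hierarchical_regression(y, X1, X2)
            deltas.append(h.delta_r2)
            pvals.append(h.f_change_pvalue)
        assert np.mean(deltas) < 0.05
        frac_sig = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 <= frac_sig <= 0.12

    def test_known_standardized_effect_recovered(self):
        # y = 0.5 * z-scored predictor + noise, n = 30: mean beta within 2 SE
        rng = np.random.default_rng(33)
        est = []
        for _ in range(500):
            n = 30
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=0)
            y = pd.Series(0.5 * z + rng.normal(size=n))
            h = hierarchical_regression(y, pd.DataFrame(index=range(n)),
                                        pd.DataFrame({"z": z}))
            est.append(h.step2.terms.loc["z", "beta"])
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.5) < 2 * se

    def test_collinear_design_warns(self, rng):
        n = 40
        x = rng.normal(size=n)
        X1 = pd.DataFrame({"a": x})
        X2 = pd.DataFrame({"b": x * (1 + 1e-12)})
        h = hierarchical_regression(pd.Series(rng.normal(size=n)), X1, X2)
        assert h.condition_warning


class TestPartialCorrelation:
    def test_no_controls_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 60))
        r, p, df = partial_correlation(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)
        assert df == 58

    def test_identical_variables_fully_correlated(self, rng):
        x = rng.normal(size=50)
        controls = pd.DataFrame({"c": rng.normal(size=50)})
        r, _, _ = partial_correlation(x, x.copy(), controls)
        assert r == pytest.approx(1.0)

    def test_matches_pingouin_reference(self, rng):
        n = 80
        z = rng.normal(size=n)
        x = z + rng.normal(size=n)
        y = 0.5 * z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        r, p, _ = partial_correlation(x, y, df[["z"]])
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_known_partial_correlation_recovered(self):
        # x = z + u, y = z + v with corr(u, v) = 0.4: partial r given z = 0.4
        rng = np.random.default_rng(34)
        est = []
        cov = np.array([[1.0, 0.4], [0.4, 1.0]])
        L = np.linalg.cholesky(cov)
        for _ in range(500):
            n = 100
            z = rng.normal(size=n)
            uv = rng.normal(size=(n, 2)) @ L.T
            r, _, _ = partial_correlation(z + uv[:, 0], z + uv[:, 1],
                                          pd.DataFrame({"z": z}))
            est.append(r)
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.4) < 2 * se + 0.01  # small-n attenuation

    def test_constant_residual_rejected(self, rng):
        z = rng.normal(size=30)
        with pytest.raises(ValueError):
            partial_correlation(2.0 * z, rng.normal(size=30),
                                pd.DataFrame({"z": z}))


class TestCovariateFixture:
    def test_shapes_and_plausible_structure(self):
        df = sample_covariates(200, seed=40)
        assert len(df) == 200
        assert df["age"].between(50, 95).mean() > 0.95
        # volumes correlate with head size; cognition declines with age
        assert df["left_ifg"].corr(df["etiv"]) > 0.15
        assert df["story_memory"].corr(df["age"]) < 0

    def test_missingness_knockout(self):
        df = sample_covariates(300, seed=41, missing_rate=0.1)
        frac = df.drop(columns="participant_id").isna().mean().mean()
        assert 0.05 < frac < 0.15
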