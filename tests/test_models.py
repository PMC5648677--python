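import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from edaphoniche.models import (
    anova_tukey,
    class_cation_summary,
    fit_cation_model,
    gaussian_aic,
    pearson_corr,
    predict_cation,
    stepwise_aic,
)


class TestClassCationSummary:
    def test_hand_arithmetic_and_flagging(self):
        out = class_cation_summary(["A"] * 3, [1.0, 10.0, 100.0])
        row = out.iloc[0]
        assert (row["min"], row["max"]) == (1.0, 100.0)
        assert row["mean"] == pytest.approx(37.0)
        assert row["orders_of_magnitude"] == pytest.approx(2.0)
        assert bool(row["flagged"])

    def test_singleton_class(self):
        out = class_cation_summary(["A"], [5.0])
        row = out.iloc[0]
        assert row["min"] == row["max"] == row["mean"] == 5.0
        assert row["orders_of_magnitude"] == 0.0 and not row["flagged"]

    def test_ordered_by_mean_and_permutation_invariant(self):
        classes = ["hi", "lo", "hi", "lo"]
        cation = [20.0, 1.0, 30.0, 2.0]
        out = class_cation_summary(classes, cation)
        assert out["dominant_class"].tolist() == ["lo", "hi"]
        perm = np.random.default_rng(0).permutation(4)
        out2 = class_cation_summary(np.array(classes)[perm], np.array(cation)[perm])
        pd.testing.assert_frame_equal(out, out2)

    def test_no_classified_plots_rejected(self):
        with pytest.raises(ValueError):
            class_cation_summary([None], [np.nan])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f_unit_p(self):
        res = anova_tukey([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.tukey_p.loc["A", "B"] == pytest.approx(1.0)

    def test_hand_anova_decomposition(self):
        """Three equally spaced groups: between-SS 72 on 2 df, within-SS 6
        on 6 df, hence F = 36/1 = 27; p from the F(2,6) law."""
        vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = anova_tukey(vals, groups)
        assert res.f_statistic == pytest.approx(27.0)
        assert res.df == (2, 6)
        assert res.p_value == pytest.approx(stats.f.sf(27.0, 2, 6))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1, 2, 3], ["A"] * 3)

    def test_small_groups_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping groups"):
            res = anova_tukey([1, 2, 3, 4, 9], ["A", "A", "B", "B", "C"])
        assert res.dropped == ["C"]
        assert res.groups == ["A", "B"]

    def test_tukey_kramer_reduces_to_hsd_on_balanced_design(self):
        """On equal group sizes the Tukey-Kramer p-values must agree with
        classical Tukey HSD (statsmodels) to 1e-6."""
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(m, 1.0, 8) for m in (0.0, 0.5, 2.0)])
        groups = np.repeat(["A", "B", "C"], 8)
        res = anova_tukey(vals, groups)
        sm_res = pairwise_tukeyhsd(vals, groups)
        for (g1, g2), p_sm in zip(
            itertools.combinations(["A", "B", "C"], 2), sm_res.pvalues
        ):
            assert res.tukey_p.loc[g1, g2] == pytest.approx(p_sm, abs=1e-6)


class TestPearson:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson_corr(x, x)[0] == pytest.approx(1.0)
        assert pearson_corr(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computation(self):
        r, _ = pearson_corr([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(3 / np.sqrt(28 / 3))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1, 2, 3], [5, 5, 5])


def _random_design(rng, n, p):
    X = pd.DataFrame(
        rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)]
    )
    return X


class TestStepwiseAic:
    def test_perfect_predictor_selected_with_unit_slope(self):
        rng = np.random.default_rng(0)
        X = _random_design(rng, 200, 4)
        data = X.copy()
        data["cation_cmolkg"] = np.exp(X["x2"])
        fit = fit_cation_model(data, list(X.columns))
        assert fit.selected == ["x2"]
        assert fit.coefficients["x2"] == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_final_aic_never_above_either_endpoint(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            X = _random_design(rng, 120, 5)
            y = rng.standard_normal(120)
            sel = stepwise_aic(y, X)
            ones = np.ones((120, 1))
            aic_sel = gaussian_aic(y, np.column_stack([ones, X[sel].to_numpy()]) if sel else ones)
            aic_empty = gaussian_aic(y, ones)
            aic_full = gaussian_aic(y, np.column_stack([ones, X.to_numpy()]))
            assert aic_sel <= min(aic_empty, aic_full) + 1e-9

    def test_matches_exhaustive_all_subsets_on_orthogonal_designs(self):
        """With orthogonal candidates forward-backward moves are independent,
        so the procedure must reach the global all-subsets AIC minimum."""
        rng = np.random.default_rng(2)
        for trial in range(10):
            n, p = 64, 6
            # orthogonal columns via QR
            Q, _ = np.linalg.qr(rng.standard_normal((n, p + 1)))
            X = pd.DataFrame(Q[:, 1:], columns=[f"x{i}" for i in range(p)])
            beta = rng.choice([0.0, 0.0, 1.0], p)
            y = X.to_numpy() @ beta + 0.2 * rng.standard_normal(n)
            sel = set(stepwise_aic(y, X))
            ones = np.ones((n, 1))
            best = min(
                (
                    gaussian_aic(
                        y,
                        np.column_stack([ones] + [X[c].to_numpy() for c in subset])
                        if subset
                        else ones,
                    ),
                    set(subset),
                )
                for r in range(p + 1)
                for subset in itertools.combinations(X.columns, r)
            )
            got = gaussian_aic(
                y,
                np.column_stack([ones] + [X[c].to_numpy() for c in sel]) if sel else ones,
            )
            assert got == pytest.approx(best[0], abs=1e-9)

    def test_nuisance_predictors_rarely_selected(self):
        """y = 2 p1 + noise: the true predictor is always kept, each pure
        noise predictor enters in under 30% of seeded replicates."""
        n_reps, n = 100, 500
        hits = np.zeros(5)
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            X = _random_design(rng, n, 6)
            data = X.copy()
            data["cation_cmolkg"] = np.exp(2.0 * X["x0"] + 0.1 * rng.standard_normal(n))
            fit = fit_cation_model(data, list(X.columns))
            assert "x0" in fit.selected
            assert 1.9 <= fit.coefficients["x0"] <= 2.1
            for j in range(1, 6):
                hits[j - 1] += f"x{j}" in fit.selected
        assert (hits / n_reps < 0.30).all()

    def test_useless_predictor_costs_about_two_aic(self):
        rng = np.random.default_rng(5)
        n = 400
        y = rng.standard_normal(n)
        ones = np.ones((n, 1))
        junk = rng.standard_normal((n, 1))
        a0 = gaussian_aic(y, ones)
        a1 = gaussian_aic(y, np.column_stack([ones, junk]))
        # likelihood gain of one random regressor is O(1); penalty is +2
        assert 0.0 < a1 - a0 <= 2.0


class TestFitAndPredict:
    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(7)
        X = _random_design(rng, 300, 3)
        data = X.copy()
        logy = 1.0 + X.to_numpy() @ np.array([0.5, -1.0, 2.0]) + 0.05 * rng.standard_normal(300)
        data["cation_cmolkg"] = np.exp(logy)
        fit = fit_cation_model(data, list(X.columns), start="full")
        Xd = np.column_stack([np.ones(300), data[fit.selected].to_numpy()])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ logy)
        got = np.array([fit.intercept] + [fit.coefficients[c] for c in fit.selected])
        np.testing.assert_allclose(got, beta, rtol=1e-8)

    def test_nonpositive_response_dropped_with_warning(self):
        rng = np.random.default_rng(8)
        X = _random_design(rng, 50, 2)
        data = X.copy()
        data["cation_cmolkg"] = np.exp(X["x0"])
        data.loc[data.index[:5], "cation_cmolkg"] = -1.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_cation_model(data, list(X.columns))
        assert fit.n == 45 and fit.n_dropped == 5

    def test_predictions_match_explicit_dot_product(self):
        rng = np.random.default_rng(9)
        X = _random_design(rng, 100, 4)
        data = X.copy()
        data["cation_cmolkg"] = np.exp(0.3 + X.to_numpy() @ np.array([1.0, 0.0, -0.7, 0.0]))
        fit = fit_cation_model(data, list(X.columns))
        new = _random_design(rng, 50, 4)
        grad = predict_cation(fit, new)
        expected = fit.intercept + sum(
            fit.coefficients[c] * new[c].to_numpy() for c in fit.selected
        )
        np.testing.assert_allclose(grad.values.to_numpy(), expected, rtol=1e-12)

    def test_training_row_reproduced_on_noise_free_fit(self):
        rng = np.random.default_rng(10)
        X = _random_design(rng, 60, 2)
        data = X.copy()
        data["cation_cmolkg"] = np.exp(2.0 + 3.0 * X["x0"])
        fit = fit_cation_model(data, list(X.columns))
        grad = predict_cation(fit, X)
        np.testing.assert_allclose(
            grad.values.to_numpy(), np.log(data["cation_cmolkg"]), rtol=1e-10
        )

    def test_all_zero_predictor_row_gives_intercept(self):
        rng = np.random.default_rng(11)
        X = _random_design(rng, 60, 2)
        data = X.copy()
        data["cation_cmolkg"] = np.exp(1.5 + X["x1"])
        fit = fit_cation_model(data, list(X.columns))
        zero = pd.DataFrame({"x0": [0.0], "x1": [0.0]})
        assert predict_cation(fit, zero).values.iloc[0] == pytest.approx(fit.intercept)

    def test_missing_gradient_values_warned(self):
        rng = np.random.default_rng(12)
        X = _random_design(rng, 60, 2)
        data = X.copy()
        data["cation_cmolkg"] = np.exp(X["x0"])
        fit = fit_cation_model(data, list(X.columns))
        new = pd.DataFrame({"x0": [1.0, np.nan], "x1": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="predictions missing"):
            grad = predict_cation(fit, new)
        assert np.isnan(grad.values.iloc[1])
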