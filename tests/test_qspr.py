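"""QSPR regression harness: data loading, the five model families, metrics
and equation rendering."""

import warnings

import numpy as np
import pandas as pd
import pytest

from revent.qspr import (
    ConstantPredictionWarning,
    FitMetrics,
    QSPRModel,
    QSPRResults,
    RankDeficiencyWarning,
    ZeroVarianceDescriptorWarning,
    compare_models,
    equation_text,
    evaluate,
    fit,
    lasso_lambda_max,
    load_qspr_tables,
    loocv_grid_search,
)
from revent.errors import (
    AlignmentError,
    EquationUnavailableError,
    RegressionError,
)


def synthetic_linear(n=50, beta=(1.0, -2.0, 0.5), sigma=0.0, seed=11):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, len(beta))),
        columns=[f"x{i+1}" for i in range(len(beta))],
        index=[f"r{i}" for i in range(n)],
    )
    y = pd.Series(
        X.to_numpy() @ np.asarray(beta) + 3.0 + sigma * rng.normal(size=n),
        index=X.index,
        name="y",
    )
    return X, y


class TestPackagedTables:
    def test_shapes_and_columns(self):
        X, Y = load_qspr_tables()
        assert X.shape == (13, 9)
        assert list(X.columns) == ["AZI", "M1", "M2", "mM2", "H", "ReZG3", "SDD", "I", "F"]
        assert Y.shape == (13, 11)
        assert list(Y.columns) == ["BP", "EoV", "FP", "MR", "MV", "P", "MW", "MM", "PSA", "HAC", "C"]
        assert not X.isna().any().any() and not Y.isna().any().any()

    def test_known_cells(self):
        X, Y = load_qspr_tables()
        assert Y.loc["Anastrozole", "MW"] == 293.4
        assert Y.loc["Thiotepa", "HAC"] == 11
        assert X.loc["Letrozole", "M1"] == 112

    def test_shuffled_rows_align_by_name(self):
        X, Y = load_qspr_tables()
        shuffled = Y.sample(frac=1, random_state=4)
        model = QSPRModel.from_tables(X, shuffled, target="BP")
        assert list(model.X.index) == list(model.y.index)


class TestOls:
    def test_exact_linear_data(self):
        X = pd.DataFrame({"x1": [0.0, 1.0, 2.0, 3.0]}, index=list("abcd"))
        y = pd.Series([3.0, 5.0, 7.0, 9.0], index=list("abcd"), name="y")
        res = fit(X, y, method="ols")
        assert res.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(3.0, abs=1e-10)
        assert res.metrics().mse == pytest.approx(0.0, abs=1e-16)

    def test_normal_equation_orthogonality(self):
        X, y = synthetic_linear(sigma=0.5, seed=3)
        res = fit(X, y, method="ols")
        resid = (y - res.predict(X)).to_numpy()
        design = np.column_stack([np.ones(len(X)), X.to_numpy()])
        assert np.abs(design.T @ resid).max() < 1e-8

    def test_rank_deficient_warns_minimum_norm(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(3, 5)), columns=list("abcde"))
        y = pd.Series(rng.normal(size=3), name="y")
        with pytest.warns(RankDeficiencyWarning):
            res = fit(X, y, method="ols")
        # interpolates despite deficiency
        assert res.metrics().mse == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery(self):
        X, y = synthetic_linear(sigma=0.0)
        for method, hp in [("ols", {}), ("ridge", {"lam": 1e-8}),
                           ("lasso", {"lam": 1e-10}), ("enet", {"lam": 1e-10})]:
            res = fit(X, y, method=method, hyperparameters=hp)
            np.testing.assert_allclose(
                res.coefficients.to_numpy(), [1.0, -2.0, 0.5], atol=1e-4
            )

    def test_noisy_recovery_within_three_standard_errors(self):
        X, y = synthetic_linear(sigma=0.1, seed=11)
        res = fit(X, y, method="ols")
        design = np.column_stack([np.ones(len(X)), X.to_numpy()])
        resid = (y - res.predict(X)).to_numpy()
        dof = len(y) - design.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))[1:]
        for est, true, s in zip(res.coefficients, (1.0, -2.0, 0.5), se):
            assert abs(est - true) <= 3 * s


class TestPenalizedFits:
    def test_ridge_limit_matches_ols(self):
        X, y = synthetic_linear(sigma=0.3, seed=7)
        ols = fit(X, y, method="ols")
        ridge = fit(X, y, method="ridge", hyperparameters={"lam": 1e-10})
        np.testing.assert_allclose(
            ridge.coefficients.to_numpy(), ols.coefficients.to_numpy(), atol=1e-6
        )

    def test_lasso_full_shrinkage_at_lambda_max(self):
        X, y = synthetic_linear(sigma=0.5, seed=5)
        lam_max = lasso_lambda_max(X, y)
        res = fit(X, y, method="lasso", hyperparameters={"lam": lam_max * 1.001})
        assert (res.coefficients == 0).all()
        np.testing.assert_allclose(res.predict(X), y.mean(), atol=1e-10)

    def test_ridge_norm_monotone_in_penalty(self):
        X, y = synthetic_linear(sigma=0.5, seed=13)
        norms = [
            np.linalg.norm(fit(X, y, "ridge", {"lam": lam}).coefficients)
            for lam in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_lasso_sparsity_monotone_along_path(self):
        X, y = synthetic_linear(n=40, beta=(2.0, -1.0, 0.5, 0.0, 0.25), sigma=0.3, seed=2)
        lam_max = lasso_lambda_max(X, y)
        path = np.geomspace(lam_max * 1e-4, lam_max * 1.1, 10)
        nnz = [
            int((fit(X, y, "lasso", {"lam": lam}).coefficients != 0).sum())
            for lam in path
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))
        assert nnz[-1] == 0

    def test_ridge_cannot_beat_ols_in_sample(self):
        X, y = synthetic_linear(n=30, beta=(1.5,), sigma=0.4, seed=21)
        mse_ols = fit(X, y, "ols").metrics().mse
        mse_ridge = fit(X, y, "ridge", {"lam": 5.0}).metrics().mse
        assert mse_ridge >= mse_ols - 1e-12

    def test_standardized_and_original_scale_predictions_agree(self):
        X, Y = load_qspr_tables()
        for method, hp in [("ridge", {}), ("lasso", {}), ("enet", {})]:
            res = fit(X, Y["BP"], method=method, hyperparameters=hp)
            # recompute via standardized parameters
            mu = np.array([res.standardization["mean"][c] for c in res.kept_columns])
            sd = np.array([res.standardization["scale"][c] for c in res.kept_columns])
            beta_std = res.coefficients.to_numpy() * sd
            b0_std = res.intercept + float(beta_std @ (mu / sd))
            Xs = (X[res.kept_columns].to_numpy() - mu) / sd
            np.testing.assert_allclose(
                Xs @ beta_std + b0_std, res.predict(X).to_numpy(), atol=1e-8
            )

    def test_zero_variance_descriptor_dropped(self):
        X, y = synthetic_linear(sigma=0.2, seed=9)
        X["const"] = 1.0
        with pytest.warns(ZeroVarianceDescriptorWarning):
            res = fit(X, y, method="ridge")
        assert "const" not in res.coefficients.index

    def test_invalid_hyperparameters(self):
        X, y = synthetic_linear()
        with pytest.raises(RegressionError):
            fit(X, y, "ridge", {"lam": -1.0})
        with pytest.raises(RegressionError):
            fit(X, y, "enet", {"mix": 1.5})
        with pytest.raises(RegressionError):
            fit(X, y, "svr", {"C": 0.0})


class TestSvr:
    def test_rbf_fits_and_predicts(self):
        X, Y = load_qspr_tables()
        res = fit(X, Y["BP"], method="svr")
        assert res.coefficients is None
        m = res.metrics()
        assert np.isfinite(m.mse) and -1 <= m.pearson_r <= 1

    def test_linear_kernel_exposes_coefficients(self):
        X, y = synthetic_linear(sigma=0.1, seed=17)
        res = fit(X, y, method="svr", hyperparameters={"kernel": "linear"})
        assert res.coefficients is not None
        np.testing.assert_allclose(
            res.predict(X).to_numpy(),
            X.to_numpy() @ res.coefficients.to_numpy() + res.intercept,
            atol=1e-6,
        )


class TestEvaluate:
    def test_perfect_fit(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        y = pd.Series([2.0, 4.0, 6.0], name="y")
        m = evaluate(fit(X, y, "ols"), X, y)
        assert m == FitMetrics(pearson_r=pytest.approx(1.0),
                               r_squared=pytest.approx(1.0),
                               mse=pytest.approx(0.0, abs=1e-20))

    def test_hand_computed_three_point_case(self):
        # observations (1,2,3) against predictions (1,2,4)
        X = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        y = pd.Series([1.0, 2.0, 3.0], name="y")
        res = QSPRResults(
            model=QSPRModel(X, y, method="ols"),
            coefficients=pd.Series({"x": 1.0}),
            intercept=0.0,
            kept_columns=["x"],
            standardization=None,
        )
        m = res.metrics(X, y)
        assert m.mse == pytest.approx(1 / 3)
        assert m.r_squared == pytest.approx(0.5)

    def test_constant_prediction_flagged(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        y = pd.Series([1.0, 2.0, 4.0], name="y")
        res = QSPRResults(
            model=QSPRModel(X, y, method="ols"),
            coefficients=pd.Series({"x": 0.0}),
            intercept=float(y.mean()),
            kept_columns=["x"],
            standardization=None,
        )
        with pytest.warns(ConstantPredictionWarning):
            m = res.metrics(X, y)
        assert m.pearson_r == 0.0
        assert m.r_squared == pytest.approx(0.0)

    def test_misaligned_rows_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        y = pd.Series([1.0, 2.0], index=["a", "zzz"], name="y")
        with pytest.raises(AlignmentError):
            fit(X, y, "ols")


class TestCompareModels:
    def test_exact_linear_data_all_methods(self):
        X, y = synthetic_linear(sigma=0.0, seed=1)
        table = compare_models(X, y, methods=("ols", "ridge", "lasso", "enet", "svr"))
        assert list(table["model"]) == ["ols", "ridge", "lasso", "enet", "svr"]
        assert table.set_index("model").loc["ols", "mse"] == pytest.approx(0.0, abs=1e-16)

    def test_empty_methods(self):
        X, y = synthetic_linear()
        assert compare_models(X, y, methods=()).empty

    def test_bitwise_reproducibility(self):
        X, Y = load_qspr_tables()
        t1 = compare_models(X, Y["EoV"], seed=42)
        t2 = compare_models(X, Y["EoV"], seed=42)
        pd.testing.assert_frame_equal(t1, t2, check_exact=True)


class TestEquationText:
    def _hand_fit(self, coefs, intercept, target="BP"):
        names = list(coefs)
        X = pd.DataFrame(np.eye(max(len(names), 2), len(names)), columns=names)
        y = pd.Series(np.arange(len(X), dtype=float), name=target)
        return QSPRResults(
            model=QSPRModel(X, y, method="ols"),
            coefficients=pd.Series(coefs),
            intercept=intercept,
            kept_columns=names,
            standardization=None,
        )

    def test_single_descriptor_format(self):
        res = self._hand_fit({"E_ReZG3": 165.787}, 550.12)
        assert equation_text(res) == "BP = 550.1200 + (165.7870) E_ReZG3"

    def test_negative_coefficient_kept_in_parentheses(self):
        res = self._hand_fit({"E_R-1": -360.6798, "E_ReZG3": 479.8992}, 319.04, target="MV")
        assert equation_text(res) == (
            "MV = 319.0400 + (-360.6798) E_R-1 + (479.8992) E_ReZG3"
        )

    def test_zero_coefficients_omitted(self):
        res = self._hand_fit({"a": 0.0, "b": 0.0}, 28.7, target="HAC")
        assert equation_text(res) == "HAC = 28.7000"

    def test_svr_rbf_has_no_equation(self):
        X, Y = load_qspr_tables()
        res = fit(X, Y["BP"], method="svr")
        with pytest.raises(EquationUnavailableError):
            equation_text(res)


class TestLoocv:
    def test_grid_search_returns_member_of_grid(self):
        X, y = synthetic_linear(n=20, sigma=0.3, seed=8)
        grid = [{"lam": 0.01}, {"lam": 1.0}]
        best, mse = loocv_grid_search(X, y, "ridge", grid)
        assert best in grid and mse > 0

    def test_empty_grid_rejected(self):
        X, y = synthetic_linear()
        with pytest.raises(RegressionError):
            loocv_grid_search(X, y, "ridge", [])


class TestSummary:
    def test_summary_mentions_method_and_metrics(self):
        X, Y = load_qspr_tables()
        text = fit(X, Y["BP"], method="ridge").summary()
        assert "ridge" in text and "R-squared" in text and "ReZG3" in text
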