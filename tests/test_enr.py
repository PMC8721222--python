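"""Elastic net: solver limits and grouping effect, grid mechanics, and the
repeated nested cross-validation protocol."""

import numpy as np
import pandas as pd
import pytest

from wheatfusion import enr
from wheatfusion.exceptions import ValidationError
from wheatfusion.indices import FeatureTable


def ols_solution(X, y):
    """Closed-form least squares with intercept (normal equations oracle)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(X1.T @ X1, X1.T @ y)


def enet_objective(X, y, beta, intercept, lambda2, lambda1=0.0):
    r = y - (X @ beta + intercept)
    return r @ r + lambda2 * beta @ beta + lambda1 * np.abs(beta).sum()


@pytest.fixture
def toy(rng):
    X = rng.normal(size=(20, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + 0.1 * rng.normal(size=20)
    return X, y


class TestFitLimits:
    def test_zero_fraction_gives_intercept_only_model(self, toy):
        X, y = toy
        model = enr.enr_fit(X, y, enr.ENRHyper(0.5, 0.0))
        assert np.all(model.coef_.to_numpy() == 0.0)
        np.testing.assert_allclose(model.predict(X), np.full(20, y.mean()))

    def test_ols_limit_matches_normal_equations(self, toy):
        X, y = toy
        model = enr.enr_fit(X, y, enr.ENRHyper(0.0, 1.0))
        expected = ols_solution(X, y)
        np.testing.assert_allclose(model.intercept_, expected[0], atol=1e-8)
        np.testing.assert_allclose(model.coef_.to_numpy(), expected[1:], atol=1e-8)

    def test_duplicated_column_grouping_effect(self, toy):
        X, y = toy
        Xd = np.column_stack([X, X[:, 0]])
        for frac in (0.3, 0.7):
            model = enr.enr_fit(Xd, y, enr.ENRHyper(0.3, frac))
            b = model.coef_.to_numpy()
            assert b[0] == pytest.approx(b[3], abs=1e-6)

    def test_ols_residuals_orthogonal_to_columns(self, toy):
        X, y = toy
        model = enr.enr_fit(X, y, enr.ENRHyper(0.0, 1.0))
        resid = y - model.predict(X)
        np.testing.assert_allclose(X.T @ resid, np.zeros(3), atol=1e-8)

    def test_objective_no_worse_than_zero_and_ols(self, rng):
        """In the constrained view the zero vector is always feasible, and at
        fraction = 1 the solution is the ridge optimum, which beats OLS on
        the penalized objective (standardized coordinates)."""
        for _ in range(10):
            n, p = 30, 5
            X = rng.normal(size=(n, p))
            X = (X - X.mean(0)) / X.std(0)
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            lam2 = float(rng.uniform(0.01, 1.0))
            frac = float(rng.uniform(0.05, 0.95))
            model = enr.enr_fit(X, y, enr.ENRHyper(lam2, frac))
            obj = enet_objective(X, y, model.coef_.to_numpy(), model.intercept_, lam2)
            obj_zero = enet_objective(X, y, np.zeros(p), y.mean(), lam2)
            assert obj <= obj_zero + 1e-9
            full = enr.enr_fit(X, y, enr.ENRHyper(lam2, 1.0))
            obj_full = enet_objective(X, y, full.coef_.to_numpy(), full.intercept_, lam2)
            ols = ols_solution(X, y)
            obj_ols = enet_objective(X, y, ols[1:], ols[0], lam2)
            assert obj_full <= obj_ols + 1e-9

    def test_zero_variance_column_dropped_with_warning(self, toy):
        X, y = toy
        Xz = np.column_stack([X, np.full(20, 3.0)])
        with pytest.warns(UserWarning):
            model = enr.enr_fit(Xz, y, enr.ENRHyper(0.1, 0.8))
        assert model.coef_.iloc[3] == 0.0

    def test_nonfinite_inputs_rejected(self, toy):
        X, y = toy
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            enr.enr_fit(X, y, enr.ENRHyper(0.1, 0.5))


class TestPredict:
    def test_constant_prediction_when_all_coefficients_zero(self, toy):
        X, y = toy
        model = enr.enr_fit(X, y, enr.ENRHyper(1.0, 0.0))
        np.testing.assert_allclose(model.predict(X), model.intercept_)

    def test_rowwise_independence(self, toy):
        X, y = toy
        model = enr.enr_fit(X, y, enr.ENRHyper(0.2, 0.6))
        single = model.predict(X[:1])
        stacked = model.predict(np.vstack([X[:1], X[:1]]))
        np.testing.assert_allclose(stacked, np.repeat(single, 2))

    def test_column_mismatch_rejected(self, toy):
        X, y = toy
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        model = enr.enr_fit(df, y, enr.ENRHyper(0.2, 0.6))
        with pytest.raises(ValidationError):
            model.predict(df.rename(columns={"c": "z"}))
        assert model.predict(df).shape == (20,)


class TestGrid:
    def test_cartesian_default_grid_has_900_candidates(self):
        assert len(enr.default_grid("cartesian").candidates()) == 900

    def test_paired_default_grid_has_30_candidates(self):
        assert len(enr.default_grid("paired").candidates()) == 30

    def test_paired_mode_requires_equal_lengths(self):
        with pytest.raises(ValidationError):
            enr.HyperGrid((0.1, 0.2), (0.5,), "paired")

    def test_hyper_bounds_enforced(self):
        with pytest.raises(ValidationError):
            enr.ENRHyper(-0.1, 0.5)
        with pytest.raises(ValidationError):
            enr.ENRHyper(0.1, 1.5)


class TestGridSearch:
    def test_single_candidate_returned_without_search(self, toy):
        X, y = toy
        grid = enr.HyperGrid((0.7,), (0.03,), "paired")
        best = enr.inner_grid_search(X, y, grid)
        assert best == enr.ENRHyper(0.7, 0.03)

    def test_dominating_candidate_wins(self, rng):
        n = 40
        X = rng.normal(size=(n, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + 0.05 * rng.normal(size=n)
        grid = enr.HyperGrid((0.0,), (0.0, 1.0), "cartesian")
        best = enr.inner_grid_search(
            X, y, grid, enr.CVConfig(inner_folds=4, seed=0)
        )
        assert best.fraction == 1.0  # the near-OLS candidate dominates every fold

    def test_deterministic_under_seed(self, small_table, tiny_grid):
        cfg = enr.CVConfig(inner_folds=4, seed=5)
        a = enr.grid_search(small_table.X, small_table.y, tiny_grid, cfg)
        b = enr.grid_search(small_table.X, small_table.y, tiny_grid, cfg)
        assert a.best == b.best
        np.testing.assert_allclose(a.scores["score"], b.scores["score"])


class TestNestedCV:
    def test_default_protocol_fits_500_models(self, small_table):
        grid = enr.HyperGrid((0.5,), (0.05,), "paired")
        cfg = enr.CVConfig(outer_folds=10, outer_repeats=50, inner_folds=10, seed=0)
        pred = enr.nested_cv(small_table, grid, cfg)
        assert pred.n_models == 500
        assert len(pred.fold_metrics) == 500

    def test_minimal_cv_predicts_every_plot_once(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 2)), columns=["a", "b"],
                         index=[f"p{i}" for i in range(4)])
        y = pd.Series(rng.uniform(3, 8, size=4), index=X.index)
        table = FeatureTable("toy", X, y)
        grid = enr.HyperGrid((0.1,), (0.5,), "paired")
        cfg = enr.CVConfig(outer_folds=2, outer_repeats=1, inner_folds=2, seed=0)
        pred = enr.nested_cv(table, grid, cfg)
        assert pred.n_models == 2
        assert sorted(pred.predictions["plot_id"]) == sorted(X.index)

    def test_each_plot_predicted_once_per_repeat(self, small_table, tiny_grid):
        cfg = enr.CVConfig(outer_folds=5, outer_repeats=2, inner_folds=3, seed=1)
        pred = enr.nested_cv(small_table, tiny_grid, cfg)
        counts = pred.predictions.groupby(["repeat", "plot_id"]).size()
        assert (counts == 1).all()

    def test_determinism_contract(self, small_table, tiny_grid, fast_cv):
        a = enr.nested_cv(small_table, tiny_grid, fast_cv)
        b = enr.nested_cv(small_table, tiny_grid, fast_cv)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        other = enr.nested_cv(
            small_table, tiny_grid,
            enr.CVConfig(outer_folds=5, outer_repeats=1, inner_folds=4, seed=99),
        )
        assert not a.predictions["y_pred"].equals(other.predictions["y_pred"])

    def test_rmse_at_least_mae_on_every_fold(self, small_table, tiny_grid, fast_cv):
        pred = enr.nested_cv(small_table, tiny_grid, fast_cv)
        assert (pred.fold_metrics["rmse"] >= pred.fold_metrics["mae"] - 1e-12).all()

    def test_too_few_samples_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 2)), index=list("abc"))
        y = pd.Series([4.0, 5.0, 6.0], index=list("abc"))
        with pytest.raises(ValidationError):
            enr.nested_cv(FeatureTable("t", X, y),
                          enr.HyperGrid((0.1,), (0.5,), "paired"),
                          enr.CVConfig(outer_folds=5, outer_repeats=1, inner_folds=2))


class TestConcatBaseline:
    def test_two_stages_give_44_columns(self, trial, tiny_grid, fast_cv):
        import wheatfusion as wf

        tables = {s: wf.build_feature_table(trial, s)
                  for s in ("heading", "flowering")}
        pred = enr.concat_stage_cv(tables, tiny_grid, fast_cv)
        assert pred.stage == "heading+flowering"

    def test_six_stage_design_matrix_has_132_columns(self, trial):
        import wheatfusion as wf
        from wheatfusion.synthdata import STAGES

        tables = {s: wf.build_feature_table(trial, s) for s in STAGES}
        blocks = [t.X.add_suffix(f"_{s}") for s, t in tables.items()]
        assert sum(b.shape[1] for b in blocks) == 132
        X = pd.concat(blocks, axis=1)
        assert X.shape == (180, 132)

    def test_single_stage_concat_equals_plain_nested_cv(self, small_table,
                                                        tiny_grid, fast_cv):
        concat = enr.concat_stage_cv({"heading": small_table}, tiny_grid, fast_cv)
        plain = enr.nested_cv(small_table, tiny_grid, fast_cv)
        np.testing.assert_allclose(
            concat.predictions["y_pred"], plain.predictions["y_pred"], atol=1e-10
        )

    def test_plot_mismatch_rejected(self, small_table):
        other = FeatureTable(
            "x", small_table.X.iloc[:-1].copy(), small_table.y.iloc[:-1].copy()
        )
        with pytest.raises(ValidationError):
            enr.concat_stage_cv({"a": small_table, "b": other},
                                enr.HyperGrid((0.1,), (0.5,), "paired"))
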