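"""Entropy-weight fusion: capped relative error, entropy-weight oracle
equivalence, fusion algebra, and the CV-embedded fusion protocol."""

import math

import numpy as np
import pandas as pd
import pytest

from wheatfusion import enr, ewf
from wheatfusion.exceptions import ValidationError
from wheatfusion.indices import FeatureTable


def literal_entropy_weights(E):
    """Loop implementation of the entropy-weight recipe (test oracle)."""
    m, n = len(E), len(E[0])
    k = 1.0 / math.log(n)
    P = [[E[i][j] / sum(E[i]) for j in range(n)] for i in range(m)]
    h = [-k * sum(p * math.log(p) for p in row if p > 0) for row in P]
    d = [1 - hi for hi in h]
    sd = sum(d)
    w_raw = [(1 - di / sd) / m for di in d]
    w_norm = [w / sum(w_raw) for w in w_raw]
    return np.array(h), np.array(w_raw), np.array(w_norm)


class TestRelativeError:
    def test_perfect_prediction_is_zero(self):
        assert ewf.relative_error([5.0], [5.0])[0] == 0.0

    def test_large_error_capped_at_one(self):
        assert ewf.relative_error([5.0], [12.0])[0] == 1.0

    def test_plain_value(self):
        assert ewf.relative_error([4.0], [5.0])[0] == pytest.approx(0.25)

    def test_zero_measured_yield_rejected(self):
        with pytest.raises(ValidationError):
            ewf.relative_error([0.0, 4.0], [1.0, 4.0])


class TestEntropyWeights:
    def test_uniform_errors_reach_maximal_entropy(self):
        E = pd.DataFrame([[0.2] * 5, [0.4, 0.1, 0.2, 0.05, 0.3]],
                         index=["a", "b"])
        w = ewf.entropy_stage_weights(E)
        assert w.h["a"] == pytest.approx(1.0, abs=1e-12)
        assert w.d["a"] == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_error_has_zero_entropy(self):
        E = pd.DataFrame([[1.0, 0.0, 0.0, 0.0], [0.25] * 4], index=["a", "b"])
        w = ewf.entropy_stage_weights(E)
        assert w.h["a"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_rows_share_weight_equally(self):
        row = [0.3, 0.1, 0.2, 0.4]
        w = ewf.entropy_stage_weights(pd.DataFrame([row, row], index=["a", "b"]))
        np.testing.assert_allclose(w.w_norm, [0.5, 0.5], atol=1e-12)

    def test_three_stage_oracle_equivalence(self):
        E = [[0.25, 0.25, 0.25, 0.25],
             [0.1, 0.1, 0.1, 0.1],
             [0.0, 0.8, 0.0, 0.0]]
        w = ewf.entropy_stage_weights(pd.DataFrame(E, index=list("abc")))
        h, w_raw, w_norm = literal_entropy_weights(E)
        np.testing.assert_allclose(w.h, h, atol=1e-12)
        np.testing.assert_allclose(w.w_raw, w_raw, atol=1e-12)
        np.testing.assert_allclose(w.w_norm, w_norm, atol=1e-12)

    def test_random_matrices_match_oracle(self, rng):
        for _ in range(25):
            m, n = int(rng.integers(2, 6)), int(rng.integers(2, 9))
            E = rng.uniform(0.01, 1.0, size=(m, n))
            w = ewf.entropy_stage_weights(pd.DataFrame(E))
            h, w_raw, w_norm = literal_entropy_weights(E.tolist())
            np.testing.assert_allclose(w.h, h, atol=1e-12)
            np.testing.assert_allclose(w.w_norm, w_norm, atol=1e-12)
            assert w.w_raw.sum() == pytest.approx((m - 1) / m, abs=1e-12)
            assert w.w_norm.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w.w_norm >= 0).all()
            np.testing.assert_allclose(w.P.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_error_stage_gets_largest_weight(self):
        E = pd.DataFrame([[0.0, 0.0, 0.0], [0.5, 0.1, 0.05]], index=["perfect", "noisy"])
        with pytest.warns(UserWarning):
            w = ewf.entropy_stage_weights(E)
        assert w.h["perfect"] == 1.0
        assert w.w_norm["perfect"] == w.w_norm.max()

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValidationError):
            ewf.entropy_stage_weights(pd.DataFrame([[0.1, 0.2]]))
        with pytest.raises(ValidationError):
            ewf.entropy_stage_weights(pd.DataFrame([[0.1], [0.2]]))
        with pytest.raises(ValidationError):
            ewf.entropy_stage_weights(pd.DataFrame([[0.5, 1.5], [0.1, 0.2]]))


class TestFusion:
    def test_equal_weights_give_arithmetic_mean(self):
        preds = pd.DataFrame({"a": [4.0, 6.0], "b": [6.0, 8.0]})
        fused = ewf.fuse_predictions(preds, pd.Series({"a": 0.5, "b": 0.5}))
        np.testing.assert_allclose(fused, [5.0, 7.0])

    def test_unit_weight_returns_that_stage(self):
        preds = pd.DataFrame({"a": [4.0, 6.0], "b": [9.0, 1.0]})
        fused = ewf.fuse_predictions(preds, pd.Series({"a": 1.0, "b": 0.0}))
        np.testing.assert_allclose(fused, preds["a"])

    def test_fused_value_within_stage_envelope(self, rng):
        preds = pd.DataFrame(rng.uniform(3, 9, size=(20, 4)),
                             columns=list("abcd"))
        raw = rng.uniform(0.1, 1.0, size=4)
        w = pd.Series(raw / raw.sum(), index=list("abcd"))
        fused = ewf.fuse_predictions(preds, w)
        assert (fused >= preds.min(axis=1) - 1e-12).all()
        assert (fused <= preds.max(axis=1) + 1e-12).all()

    def test_stage_weight_mismatch_rejected(self):
        preds = pd.DataFrame({"a": [4.0], "b": [5.0]})
        with pytest.raises(ValidationError):
            ewf.fuse_predictions(preds, pd.Series({"a": 1.0}))
        with pytest.raises(ValidationError):
            ewf.fuse_predictions(preds, pd.Series({"a": 0.9, "b": 0.3}))


class TestCombinations:
    def test_canonical_set_has_eight_members(self):
        assert len(ewf.DEFAULT_COMBINATIONS) == 8
        by_label = {c.label: c.stages for c in ewf.DEFAULT_COMBINATIONS}
        assert by_label["C1"] == ("jointing", "booting", "heading")
        assert len(by_label["C4"]) == 6

    def test_single_stage_combination_rejected(self):
        with pytest.raises(ValidationError):
            ewf.StageCombination("solo", ("heading",))

    def test_repeated_stage_rejected(self):
        with pytest.raises(ValidationError):
            ewf.StageCombination("dup", ("heading", "heading"))


def _linear_table(stage, y, coef, noise, rng, n_features=3):
    X = pd.DataFrame(
        {f"f{j}": coef * y + noise * rng.normal(size=len(y)) if j == 0
         else rng.uniform(0.1, 0.9, size=len(y))
         for j in range(n_features)},
        index=[f"p{i:03d}" for i in range(len(y))],
    )
    return FeatureTable(stage, X, pd.Series(y, index=X.index, name="y"))


class TestEwfCV:
    def test_informative_stage_outweighs_noise_stage(self, rng):
        """A stage whose features carry the yield noiselessly must receive a
        larger fusion weight than a pure-noise stage in every fold."""
        y = rng.uniform(3, 8, size=40)
        tables = {
            "clean": _linear_table("clean", y, 0.1, 0.0, rng),
            "noise": _linear_table("noise", y, 0.0, 1.0, rng),
        }
        grid = enr.HyperGrid((0.0,), (1.0,), "paired")
        cfg = enr.CVConfig(outer_folds=4, outer_repeats=1, inner_folds=3, seed=2)
        fused, weights = ewf.ewf_cv(
            tables, ewf.StageCombination("CB", ("clean", "noise")), grid, cfg
        )
        pivot = weights.pivot_table(index="fold", columns="stage", values="w_norm")
        assert (pivot["clean"] > pivot["noise"]).all()

    def test_weights_form_probability_vector_per_fold(self, rng):
        y = rng.uniform(3, 8, size=30)
        tables = {s: _linear_table(s, y, 0.1, 0.3, rng) for s in ("s1", "s2", "s3")}
        grid = enr.HyperGrid((0.1,), (0.8,), "paired")
        cfg = enr.CVConfig(outer_folds=3, outer_repeats=2, inner_folds=3, seed=4)
        fused, weights = ewf.ewf_cv(
            tables, ewf.StageCombination("CC", ("s1", "s2", "s3")), grid, cfg
        )
        sums = weights.groupby(["repeat", "fold"])["w_norm"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)
        assert (weights["w_norm"] >= 0).all()
        raw_sums = weights.groupby(["repeat", "fold"])["w_raw"].sum()
        np.testing.assert_allclose(raw_sums, 2 / 3, atol=1e-12)

    def test_missing_stage_table_rejected(self, rng):
        y = rng.uniform(3, 8, size=20)
        tables = {"s1": _linear_table("s1", y, 0.1, 0.1, rng)}
        with pytest.raises(ValidationError):
            ewf.ewf_cv(tables, ewf.StageCombination("CX", ("s1", "s2")),
                       enr.HyperGrid((0.1,), (0.5,), "paired"))


def test_fusion_beats_best_single_stage_under_equal_noise(rng):
    """With stage predictions = truth + independent equal-variance noise the
    fused test RMSE undercuts the best single stage in >= 80% of replicates
    (averaging property)."""
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        r = np.random.default_rng(1000 + rep)
        y = r.uniform(3, 8, size=180)
        stages = ["s1", "s2", "s3"]
        preds = pd.DataFrame(
            {s: y + 0.5 * r.normal(size=180) for s in stages},
            index=[f"p{i}" for i in range(180)],
        )
        train, test = np.arange(120), np.arange(120, 180)
        E = pd.DataFrame(
            {s: ewf.relative_error(y[train], preds[s].to_numpy()[train])
             for s in stages}
        ).T
        w = ewf.entropy_stage_weights(E)
        fused = ewf.fuse_predictions(preds.iloc[test], w).to_numpy()
        rmse_fused = np.sqrt(np.mean((y[test] - fused) ** 2))
        rmse_best = min(
            np.sqrt(np.mean((y[test] - preds[s].to_numpy()[test]) ** 2))
            for s in stages
        )
        wins += rmse_fused <= rmse_best
    assert wins >= 0.8 * n_rep


class TestEvaluateCombinations:
    def test_duplicate_labels_rejected(self, rng):
        y = rng.uniform(3, 8, size=20)
        tables = {s: _linear_table(s, y, 0.1, 0.2, rng) for s in ("s1", "s2")}
        combos = [ewf.StageCombination("C", ("s1", "s2")),
                  ewf.StageCombination("C", ("s2", "s1"))]
        with pytest.raises(ValidationError):
            ewf.evaluate_combinations(tables, combos,
                                      enr.HyperGrid((0.1,), (0.5,), "paired"))

    def test_empty_combination_set_rejected(self):
        with pytest.raises(ValidationError):
            ewf.evaluate_combinations({}, [], enr.HyperGrid((0.1,), (0.5,), "paired"))

    def test_comparison_table_covers_all_combinations(self, rng):
        y = rng.uniform(3, 8, size=24)
        tables = {s: _linear_table(s, y, 0.1, 0.2, rng) for s in ("s1", "s2", "s3")}
        combos = [ewf.StageCombination("A", ("s1", "s2")),
                  ewf.StageCombination("B", ("s1", "s2", "s3"))]
        grid = enr.HyperGrid((0.1,), (0.8,), "paired")
        cfg = enr.CVConfig(outer_folds=3, outer_repeats=1, inner_folds=3, seed=1)
        results, comparison = ewf.evaluate_combinations(tables, combos, grid, cfg)
        assert set(results) == {"A", "B"}
        assert list(comparison.index) == ["A", "B"]
        assert {"r2_mean", "rmse_mean", "rrmse_mean", "mae_mean"} <= set(comparison.columns)
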