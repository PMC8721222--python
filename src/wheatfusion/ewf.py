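"""Entropy-weight fusion (EWF) of multi-stage yield predictions.

Each growth stage's elastic-net model produces its own predicted yield per
plot.  EWF combines them into one prediction per plot with weights derived
from the Shannon entropy of each stage's relative-error profile over the
training plots:

    E_ij = min(|(y_j - yhat_ij)/y_j|, 1)                (capped relative error)
    P_ij = E_ij / sum_j E_ij                            (per-stage error ratios)
    h_i  = -(1/ln n) sum_j P_ij ln P_ij                 (entropy, 0*ln 0 := 0)
    d_i  = 1 - h_i                                      (variation coefficient)
    w_i  = (1/m) (1 - d_i / sum_i d_i)                  (raw weight)

A stage whose relative errors are spread evenly over plots (maximum entropy,
d_i = 0) earns the largest weight; a stage whose error concentrates on a few
plots is down-weighted.  The raw weights sum to (m-1)/m, which would bias
every fused prediction low by 1/m, so they are renormalized to sum to 1
before fusing (both are reported).  The fused prediction is the convex
combination yhat_j = sum_i w_i yhat_ij.

A stage with all-zero training errors is the limit of uniformly shrinking
errors, so it is assigned h_i = 1, d_i = 0 (largest weight) with a warning;
the entropy formula itself is undefined there.

Inside cross-validation the weights are estimated on each outer training
split only — from inner out-of-fold predictions, not resubstitution fits,
so that a heavily tuned stage cannot understate its own error — and then
applied to the held-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .enr import (
    CVConfig,
    StagePrediction,
    _derived_seed,
    _ENRPath,
    inner_grid_search,
)
from .exceptions import ValidationError
from .metrics import metric_distribution, regression_metrics

__all__ = [
    "StageCombination",
    "DEFAULT_COMBINATIONS",
    "EntropyWeights",
    "relative_error",
    "entropy_stage_weights",
    "fuse_predictions",
    "ewf_cv",
    "evaluate_combinations",
]


@dataclass(frozen=True)
class StageCombination:
    """A labelled set of >= 2 growth stages to fuse."""

    label: str
    stages: tuple

    def __post_init__(self):
        if len(self.stages) < 2:
            raise ValidationError(
                f"combination {self.label!r} needs >= 2 stages, got {self.stages}"
            )
        if len(set(self.stages)) != len(self.stages):
            raise ValidationError(f"combination {self.label!r} repeats a stage")


#: The eight canonical growth-stage combinations.
DEFAULT_COMBINATIONS = (
    StageCombination("C1", ("jointing", "booting", "heading")),
    StageCombination("C2", ("jointing", "booting", "heading", "flowering")),
    StageCombination("C3", ("jointing", "booting", "heading", "flowering", "grain_filling")),
    StageCombination("C4", ("jointing", "booting", "heading", "flowering",
                            "grain_filling", "maturity")),
    StageCombination("C5", ("booting", "heading", "flowering")),
    StageCombination("C6", ("heading", "flowering", "grain_filling")),
    StageCombination("C7", ("flowering", "grain_filling", "maturity")),
    StageCombination("C8", ("heading", "flowering", "maturity")),
)


def relative_error(y_true, y_pred):
    """Relative prediction error |(y - yhat)/y|, capped at 1.

    Vectorized; raises for any zero ``y_true`` (undefined relative error).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.any(y_true == 0):
        raise ValidationError("relative error undefined for zero measured yield")
    return np.minimum(np.abs((y_true - y_pred) / y_true), 1.0)


@dataclass
class EntropyWeights:
    """Per-stage entropy-weight decomposition.

    ``P`` holds the error-ratio rows (stages x plots, each row sums to 1),
    ``h`` the entropies, ``d = 1 - h`` the variation coefficients,
    ``w_raw`` the raw weights (sum (m-1)/m) and ``w_norm`` the renormalized
    fusion weights (sum 1).  ``k_const = 1/ln(n_plots)``.
    """

    stages: list
    P: pd.DataFrame = field(repr=False)
    h: pd.Series = field(repr=False)
    d: pd.Series = field(repr=False)
    w_raw: pd.Series = field(repr=False)
    w_norm: pd.Series = field(repr=False)
    k_const: float = 0.0


def entropy_stage_weights(error_matrix):
    """Entropy weights from a stages x plots relative-error matrix.

    ``error_matrix`` is a DataFrame (index = stages, columns = plots) with
    entries in [0, 1].  Requires >= 2 stages and >= 2 plots.
    """
    E = error_matrix
    if not isinstance(E, pd.DataFrame):
        E = pd.DataFrame(np.asarray(E, dtype=float))
    m, n = E.shape
    if m < 2 or n < 2:
        raise ValidationError(f"need >= 2 stages and >= 2 plots, got {m} x {n}")
    vals = E.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any((vals < 0) | (vals > 1)):
        raise ValidationError("relative errors must be finite and in [0, 1]")

    k_const = 1.0 / np.log(n)
    row_sums = vals.sum(axis=1)
    # errors at machine precision are exact zeros for entropy purposes: the
    # ratios P of rounding noise would otherwise carry arbitrary structure
    zero_rows = vals.max(axis=1) <= 1e-12
    if zero_rows.any():
        warnings.warn(
            f"stage(s) {list(E.index[zero_rows])} have all-zero training errors; "
            "assigned maximum entropy (h = 1, largest weight)", stacklevel=2,
        )
    P = np.full_like(vals, np.nan)
    nz = ~zero_rows
    P[nz] = vals[nz] / row_sums[nz, None]

    h = np.empty(m)
    for i in range(m):
        if zero_rows[i]:
            h[i] = 1.0
            continue
        p = P[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        h[i] = -k_const * terms.sum()
    h = np.clip(h, 0.0, 1.0)
    d = 1.0 - h
    d_sum = d.sum()
    if d_sum == 0:
        # every stage maximally entropic: equal weights
        w_raw = np.full(m, (m - 1) / m / m)
        w_norm = np.full(m, 1.0 / m)
    else:
        w_raw = (1.0 - d / d_sum) / m
        w_norm = w_raw / w_raw.sum()
    stages = list(E.index)
    return EntropyWeights(
        stages=stages,
        P=pd.DataFrame(P, index=E.index, columns=E.columns),
        h=pd.Series(h, index=E.index),
        d=pd.Series(d, index=E.index),
        w_raw=pd.Series(w_raw, index=E.index),
        w_norm=pd.Series(w_norm, index=E.index),
        k_const=float(k_const),
    )


def fuse_predictions(stage_predictions, weights):
    """Convex combination of per-stage predictions.

    ``stage_predictions`` is a DataFrame (plots x stages) or a mapping
    stage -> prediction Series; ``weights`` an :class:`EntropyWeights` or a
    Series of normalized weights covering exactly the stages present.
    """
    if isinstance(stage_predictions, dict):
        stage_predictions = pd.DataFrame(stage_predictions)
    w = weights.w_norm if isinstance(weights, EntropyWeights) else pd.Series(weights)
    if set(w.index) != set(stage_predictions.columns):
        raise ValidationError(
            f"weights cover {list(w.index)} but predictions have "
            f"{list(stage_predictions.columns)}"
        )
    if not np.isclose(w.sum(), 1.0):
        raise ValidationError(f"weights must sum to 1, got {w.sum()}")
    w = w.reindex(stage_predictions.columns)
    return stage_predictions @ w


def _inner_oof_predictions(X, y, hyper, inner_folds, seed):
    """Out-of-fold training-side predictions at a fixed hyperparameter."""
    oof = np.empty_like(y)
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        path = _ENRPath(X[tr], y[tr], hyper.lambda2)
        beta, b0 = path.solution(hyper.fraction, refine=False)
        oof[te] = X[te] @ beta + b0
    return oof


def ewf_cv(feature_tables, combination, grid, cv_config=None):
    """Entropy-weight fusion evaluated inside the outer CV protocol.

    Per outer repeat/fold: each member stage's elastic net is tuned and
    fitted on the outer-train split only; its training-side errors come from
    inner out-of-fold predictions; the resulting entropy weights fuse the
    per-stage predictions on the held-out fold.  Returns
    ``(fused_prediction, weights_table)`` where ``weights_table`` records
    h, d, raw and normalized weight per (repeat, fold, stage).
    """
    cv = cv_config or CVConfig()
    missing = [s for s in combination.stages if s not in feature_tables]
    if missing:
        raise ValidationError(f"no feature table for stage(s) {missing}")
    tables = {s: feature_tables[s] for s in combination.stages}
    first = tables[combination.stages[0]]
    plot_ids = first.plot_ids
    y = first.y.to_numpy(dtype=float)
    for s, t in tables.items():
        if t.plot_ids != plot_ids or not np.allclose(t.y.to_numpy(), y):
            raise ValidationError(f"stage {s!r} plots/yields do not match")
    Xs = {s: t.X.to_numpy(dtype=float) for s, t in tables.items()}
    n = len(y)
    if n < cv.outer_folds:
        raise ValidationError(f"{n} samples cannot form {cv.outer_folds} outer folds")

    pred_rows, metric_rows, weight_rows = [], [], []
    n_models = 0
    for rep in range(cv.outer_repeats):
        kf = KFold(n_splits=cv.outer_folds, shuffle=True,
                   random_state=_derived_seed(cv.seed, rep))
        for fold, (tr, te) in enumerate(kf.split(y)):
            E_rows, test_preds = {}, {}
            for si, stage in enumerate(combination.stages):
                X = Xs[stage]
                inner_cfg = CVConfig(
                    outer_folds=cv.outer_folds, outer_repeats=cv.outer_repeats,
                    inner_folds=cv.inner_folds, inner_metric=cv.inner_metric,
                    seed=_derived_seed(cv.seed, rep, fold, 1, si),
                )
                try:
                    hyper = inner_grid_search(X[tr], y[tr], grid, inner_cfg)
                    oof = _inner_oof_predictions(
                        X[tr], y[tr], hyper, cv.inner_folds,
                        _derived_seed(cv.seed, rep, fold, 2, si),
                    )
                    path = _ENRPath(X[tr], y[tr], hyper.lambda2)
                    beta, b0 = path.solution(hyper.fraction, refine=True)
                except Exception as exc:
                    raise ValidationError(
                        f"stage {stage!r} failed in repeat {rep}, fold {fold}: {exc}"
                    ) from exc
                E_rows[stage] = relative_error(y[tr], oof)
                test_preds[stage] = X[te] @ beta + b0
                n_models += 1
            E = pd.DataFrame(
                np.vstack([E_rows[s] for s in combination.stages]),
                index=list(combination.stages),
                columns=[plot_ids[i] for i in tr],
            )
            weights = entropy_stage_weights(E)
            fused = fuse_predictions(
                pd.DataFrame(test_preds, index=[plot_ids[i] for i in te]), weights
            ).to_numpy()
            ms = regression_metrics(y[te], fused)
            metric_rows.append(
                {"repeat": rep, "fold": fold, "r2": ms.r2, "rmse": ms.rmse,
                 "rrmse": ms.rrmse, "mae": ms.mae}
            )
            for stage in combination.stages:
                weight_rows.append(
                    {"repeat": rep, "fold": fold, "stage": stage,
                     "h": weights.h[stage], "d": weights.d[stage],
                     "w_raw": weights.w_raw[stage], "w_norm": weights.w_norm[stage]}
                )
            for j, idx in enumerate(te):
                pred_rows.append(
                    {"plot_id": plot_ids[idx], "repeat": rep, "fold": fold,
                     "y_true": y[idx], "y_pred": fused[j]}
                )
    fused_pred = StagePrediction(
        stage=combination.label,
        predictions=pd.DataFrame(pred_rows),
        fold_metrics=pd.DataFrame(metric_rows),
        n_models=n_models,
    )
    return fused_pred, pd.DataFrame(weight_rows)


def evaluate_combinations(feature_tables, combinations, grid, cv_config=None):
    """Run :func:`ewf_cv` for every combination and tabulate the metrics.

    Returns ``(results, comparison)``: ``results`` maps label ->
    (fused StagePrediction, weights table); ``comparison`` is a DataFrame
    with the mean and sd of each test metric per combination.
    """
    combinations = list(combinations)
    if not combinations:
        raise ValidationError("empty combination set")
    labels = [c.label for c in combinations]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate combination labels in {labels}")
    results, rows = {}, []
    for combo in combinations:
        fused, weights = ewf_cv(feature_tables, combo, grid, cv_config)
        results[combo.label] = (fused, weights)
        summary = metric_distribution(fused.fold_metrics)
        row = {"combination": combo.label, "stages": "+".join(combo.stages)}
        for metric in ("r2", "rmse", "rrmse", "mae"):
            row[f"{metric}_mean"] = summary.loc[metric, "mean"]
            row[f"{metric}_sd"] = summary.loc[metric, "sd"]
        rows.append(row)
    return results, pd.DataFrame(rows).set_index("combination")
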