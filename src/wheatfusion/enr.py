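"""Elastic net regression with repeated nested cross-validation.

The elastic net estimate minimizes

    ||y - X beta||^2 + lambda2 ||beta||^2 + lambda1 ||beta||_1

over standardized predictors, but is parameterized here the way the
caret/elasticnet tradition exposes it: by the ridge penalty ``lambda2`` and
the L1 shrinkage ``fraction`` s in [0, 1], the ratio of the coefficient
L1 norm to that of the unconstrained (lambda1 = 0, i.e. ridge) solution.
s = 0 is the intercept-only model, s = 1 with lambda2 = 0 is ordinary least
squares.

Solver: for a fixed lambda2 the problem is a lasso on ridge-augmented data
(rows sqrt(lambda2) * I appended to standardized X), whose full solution
path is computed once with LARS and interpolated at the target L1 norm;
the coefficients along that path are piecewise linear in the norm, so the
interpolation is exact.  Final fits are additionally polished by coordinate
descent at the matched penalty level, which restores exact symmetry for
degenerate inputs (e.g. exactly duplicated columns) where LARS tie-breaking
is unstable.  The contract is on the optimum, not the algorithm.

Model assessment follows a repeated nested cross-validation protocol:
10 outer folds repeated 50 times (500 outer fits) by default, with an inner
10-fold grid search per outer training split so that hyperparameter tuning
never sees the held-out fold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, lars_path
from sklearn.model_selection import KFold

from .exceptions import ValidationError
from .indices import FeatureTable
from .metrics import regression_metrics

__all__ = [
    "TABLE_LAMBDA2",
    "TABLE_FRACTION",
    "ENRHyper",
    "HyperGrid",
    "CVConfig",
    "ENRModel",
    "enr_fit",
    "enr_predict",
    "inner_grid_search",
    "grid_search",
    "GridSearchResult",
    "nested_cv",
    "concat_stage_cv",
    "StagePrediction",
    "default_grid",
    "recovery_grid",
]

#: Default candidate ridge penalties (30 values, 0.05 .. 1.00).
TABLE_LAMBDA2 = (
    0.050, 0.083, 0.116, 0.148, 0.181, 0.214, 0.247, 0.279, 0.312, 0.345,
    0.378, 0.410, 0.443, 0.476, 0.509, 0.541, 0.574, 0.607, 0.640, 0.672,
    0.705, 0.738, 0.771, 0.803, 0.836, 0.869, 0.902, 0.934, 0.967, 1.000,
)

#: Default candidate L1 fractions (30 values, 0 and a geometric ladder to 0.1).
TABLE_FRACTION = (
    0.000e00, 1.000e-04, 1.280e-04, 1.638e-04, 2.096e-04, 2.683e-04,
    3.433e-04, 4.394e-04, 5.623e-04, 7.197e-04, 9.211e-04, 1.179e-03,
    1.509e-03, 1.931e-03, 2.471e-03, 3.162e-03, 4.047e-03, 5.179e-03,
    6.629e-03, 8.483e-03, 1.086e-02, 1.389e-02, 1.778e-02, 2.276e-02,
    2.913e-02, 3.728e-02, 4.771e-02, 6.105e-02, 7.814e-02, 1.000e-01,
)


@dataclass(frozen=True)
class ENRHyper:
    """One hyperparameter point: ridge penalty and L1 shrinkage fraction."""

    lambda2: float
    fraction: float

    def __post_init__(self):
        if self.lambda2 < 0:
            raise ValidationError(f"lambda2 must be >= 0, got {self.lambda2}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"fraction must lie in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class HyperGrid:
    """Candidate hyperparameters.

    ``mode="cartesian"`` crosses the two value lists (the grid-search
    convention); ``mode="paired"`` zips them element-wise (requires equal
    lengths).
    """

    lambda2_values: tuple = TABLE_LAMBDA2
    fraction_values: tuple = TABLE_FRACTION
    mode: str = "cartesian"

    def __post_init__(self):
        if not self.lambda2_values or not self.fraction_values:
            raise ValidationError("hyperparameter value lists must be non-empty")
        if self.mode not in ("cartesian", "paired"):
            raise ValidationError(f"unknown grid mode {self.mode!r}")
        if self.mode == "paired" and len(self.lambda2_values) != len(self.fraction_values):
            raise ValidationError("paired mode requires equal-length value lists")

    def candidates(self):
        """Ordered list of :class:`ENRHyper` candidates."""
        if self.mode == "paired":
            pairs = zip(self.lambda2_values, self.fraction_values)
        else:
            pairs = itertools.product(self.lambda2_values, self.fraction_values)
        return [ENRHyper(l2, f) for l2, f in pairs]


def default_grid(mode="cartesian"):
    """The default 30-value candidate lists (900 crossed / 30 paired)."""
    return HyperGrid(TABLE_LAMBDA2, TABLE_FRACTION, mode)


def recovery_grid():
    """A compact grid spanning the full shrinkage range (fractions up to 1).

    Used for parameter-recovery experiments on clean synthetic trials, where
    a near-unshrunk candidate must be reachable; the default fraction ladder
    is tailored to noisy field data and tops out at 0.1, which caps the L1
    budget well below what exact recovery needs.
    """
    return HyperGrid((0.0, 0.05, 0.5), (0.5, 0.9, 1.0), "cartesian")


@dataclass(frozen=True)
class CVConfig:
    """Nested cross-validation settings (outer folds x repeats, inner folds)."""

    outer_folds: int = 10
    outer_repeats: int = 50
    inner_folds: int = 10
    inner_metric: str = "mae"
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.outer_repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.inner_metric not in ("mae", "rmse"):
            raise ValidationError("inner_metric must be 'mae' or 'rmse'")


def _derived_seed(seed, *path):
    """Deterministic 31-bit substream seed from a base seed and a path."""
    ss = np.random.SeedSequence([int(seed)] + [int(p) for p in path])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


class _ENRPath:
    """Lasso path on ridge-augmented standardized data, for one lambda2."""

    def __init__(self, X, y, lambda2):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValidationError("non-finite values in X or y")
        if X.shape[0] < 2:
            raise ValidationError("elastic net requires at least 2 samples")
        self.n, self.p = X.shape
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.keep = self.sd > 0
        if not self.keep.all():
            warnings.warn(
                f"dropping zero-variance columns at positions "
                f"{list(np.flatnonzero(~self.keep))}", stacklevel=2,
            )
        self.y_mean = float(y.mean())
        k = int(self.keep.sum())
        self.k = k
        if k == 0:
            self._Xa = None
            return
        Xs = (X[:, self.keep] - self.mu[self.keep]) / self.sd[self.keep]
        yc = y - self.y_mean
        if lambda2 > 0:
            self._Xa = np.vstack([Xs, np.sqrt(lambda2) * np.eye(k)])
            self._ya = np.concatenate([yc, np.zeros(k)])
        else:
            self._Xa = Xs
            self._ya = yc
        with warnings.catch_warnings():
            # LARS stops early / drops regressors when residuals vanish
            # (near-perfect fits, tied columns); the interpolated + polished
            # solution is still the optimum we need.
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._alphas, _, self._coefs = lars_path(self._Xa, self._ya, method="lasso")
        norms = np.abs(self._coefs).sum(axis=0)
        self._norms = np.maximum.accumulate(norms)
        self._full = None

    def _full_solution(self):
        if self._full is None:
            self._full = np.linalg.lstsq(self._Xa, self._ya, rcond=None)[0]
        return self._full

    def _coef_std(self, fraction, refine):
        if self.k == 0 or fraction <= 0.0:
            return np.zeros(self.k)
        if fraction >= 1.0:
            return self._full_solution()
        t = fraction * self._norms[-1]
        b = np.array(
            [np.interp(t, self._norms, self._coefs[j]) for j in range(self.k)]
        )
        if not refine:
            return b
        alpha_t = float(np.interp(t, self._norms, self._alphas))
        if alpha_t <= 1e-12:
            return self._full_solution()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            en = ElasticNet(alpha=alpha_t, l1_ratio=1.0, fit_intercept=False,
                            max_iter=200_000, tol=1e-12)
            en.fit(self._Xa, self._ya)
        return en.coef_

    def solution(self, fraction, refine=False):
        """(beta, intercept) on the original predictor scale."""
        beta = np.zeros(self.p)
        if self.k:
            beta[self.keep] = self._coef_std(fraction, refine) / self.sd[self.keep]
        intercept = self.y_mean - float(self.mu @ beta)
        return beta, intercept


@dataclass
class ENRModel:
    """A fitted elastic net: coefficients on the original predictor scale."""

    coef_: pd.Series
    intercept_: float
    hyper: ENRHyper

    @property
    def feature_names(self):
        return list(self.coef_.index)

    def predict(self, X):
        """Affine prediction X @ beta + intercept.

        A DataFrame must carry exactly the training columns (any order);
        a bare array must match their number.
        """
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise ValidationError(
                    f"feature mismatch: missing {missing}, unexpected {extra}"
                )
            X = X[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.coef_):
                raise ValidationError(
                    f"expected {len(self.coef_)} columns, got {X.shape[1]}"
                )
        return X @ self.coef_.to_numpy() + self.intercept_


def enr_fit(X, y, hyper, refine=True):
    """Fit the elastic net at one (lambda2, fraction) point.

    Predictors are centered and scaled to unit variance internally (the
    response is centered); coefficients are returned on the original scale.
    Zero-variance columns are dropped with a warning and get coefficient 0.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = list(range(Xv.shape[1]))
    y = np.asarray(y, dtype=float)
    path = _ENRPath(Xv, y, hyper.lambda2)
    beta, intercept = path.solution(hyper.fraction, refine=refine)
    return ENRModel(pd.Series(beta, index=names), intercept, hyper)


def enr_predict(model, X):
    """Functional alias for :meth:`ENRModel.predict`."""
    return model.predict(X)


@dataclass
class GridSearchResult:
    """Outcome of an inner-CV grid search."""

    best: ENRHyper
    best_score: float
    scores: pd.DataFrame  # lambda2, fraction, score (mean inner-CV error)


def _fold_error(y_true, y_pred, metric):
    err = y_true - y_pred
    if metric == "mae":
        return float(np.mean(np.abs(err)))
    return float(np.sqrt(np.mean(err**2)))


def grid_search(X, y, grid, cv_config=None):
    """Score every candidate by inner k-fold CV; deterministic under the seed.

    Returns a :class:`GridSearchResult`; the winner minimizes the mean
    inner-test error (MAE by default), ties broken by candidate order.
    """
    cv = cv_config or CVConfig()
    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] < cv.inner_folds:
        raise ValidationError(
            f"{Xv.shape[0]} samples cannot form {cv.inner_folds} inner folds"
        )
    candidates = grid.candidates()
    by_lambda2 = {}
    for ci, cand in enumerate(candidates):
        by_lambda2.setdefault(cand.lambda2, []).append((ci, cand.fraction))

    kf = KFold(n_splits=cv.inner_folds, shuffle=True, random_state=_derived_seed(cv.seed))
    errors = np.zeros((len(candidates), cv.inner_folds))
    for fi, (tr, te) in enumerate(kf.split(Xv)):
        for lam2, members in by_lambda2.items():
            path = _ENRPath(Xv[tr], y[tr], lam2)
            for ci, frac in members:
                beta, b0 = path.solution(frac, refine=False)
                errors[ci, fi] = _fold_error(y[te], Xv[te] @ beta + b0, cv.inner_metric)
    mean_err = errors.mean(axis=1)
    best_idx = int(np.argmin(mean_err))  # argmin keeps the first minimum
    scores = pd.DataFrame(
        {
            "lambda2": [c.lambda2 for c in candidates],
            "fraction": [c.fraction for c in candidates],
            "score": mean_err,
        }
    )
    return GridSearchResult(candidates[best_idx], float(mean_err[best_idx]), scores)


def inner_grid_search(X_train, y_train, grid, cv_config=None):
    """Best hyperparameter point by inner CV (single candidate short-circuits)."""
    candidates = grid.candidates()
    if len(candidates) == 1:
        return candidates[0]
    return grid_search(X_train, y_train, grid, cv_config).best


@dataclass
class StagePrediction:
    """Out-of-fold predictions and per-fold test metrics for one stage.

    ``predictions`` has one row per plot per outer repeat (plot_id, repeat,
    fold, y_true, y_pred); ``fold_metrics`` one row per outer fold per repeat
    with the four test metrics and the chosen hyperparameters.
    """

    stage: str
    predictions: pd.DataFrame = field(repr=False)
    fold_metrics: pd.DataFrame = field(repr=False)
    n_models: int = 0

    def oof_mean(self):
        """Per-plot prediction averaged over repeats (one value per plot)."""
        return self.predictions.groupby("plot_id", sort=False)["y_pred"].mean()

    def mean_metrics(self):
        """Headline values: the mean of each metric over all outer folds."""
        return self.fold_metrics[["r2", "rmse", "rrmse", "mae"]].mean()


def _nested_cv_arrays(stage, X, y, plot_ids, grid, cv):
    n = len(y)
    if n < cv.outer_folds:
        raise ValidationError(f"{n} samples cannot form {cv.outer_folds} outer folds")
    pred_rows, metric_rows = [], []
    n_models = 0
    for rep in range(cv.outer_repeats):
        kf = KFold(n_splits=cv.outer_folds, shuffle=True,
                   random_state=_derived_seed(cv.seed, rep))
        for fold, (tr, te) in enumerate(kf.split(X)):
            inner_cfg = CVConfig(
                outer_folds=cv.outer_folds, outer_repeats=cv.outer_repeats,
                inner_folds=cv.inner_folds, inner_metric=cv.inner_metric,
                seed=_derived_seed(cv.seed, rep, fold, 1),
            )
            hyper = inner_grid_search(X[tr], y[tr], grid, inner_cfg)
            path = _ENRPath(X[tr], y[tr], hyper.lambda2)
            beta, b0 = path.solution(hyper.fraction, refine=True)
            y_pred = X[te] @ beta + b0
            n_models += 1
            ms = regression_metrics(y[te], y_pred)
            metric_rows.append(
                {"repeat": rep, "fold": fold, "r2": ms.r2, "rmse": ms.rmse,
                 "rrmse": ms.rrmse, "mae": ms.mae,
                 "lambda2": hyper.lambda2, "fraction": hyper.fraction}
            )
            for j, idx in enumerate(te):
                pred_rows.append(
                    {"plot_id": plot_ids[idx], "repeat": rep, "fold": fold,
                     "y_true": y[idx], "y_pred": y_pred[j]}
                )
    return StagePrediction(
        stage=stage,
        predictions=pd.DataFrame(pred_rows),
        fold_metrics=pd.DataFrame(metric_rows),
        n_models=n_models,
    )


def nested_cv(feature_table, grid, cv_config=None):
    """Repeated nested cross-validation of the elastic net on one stage.

    For every outer repeat the plots are randomly split into
    ``cv.outer_folds`` folds; each fold is predicted by a model tuned (inner
    grid search) and refitted on the remaining folds only.  Total outer fits
    = outer_folds x outer_repeats (500 under the defaults).  Same seed means
    identical folds and results.
    """
    cv = cv_config or CVConfig()
    X = feature_table.X.to_numpy(dtype=float)
    y = feature_table.y.to_numpy(dtype=float)
    return _nested_cv_arrays(feature_table.stage, X, y, feature_table.plot_ids, grid, cv)


def concat_stage_cv(feature_tables, grid, cv_config=None, label=None):
    """Nested CV on horizontally concatenated multi-stage features.

    ``feature_tables`` maps stage -> :class:`FeatureTable`; all tables must
    cover the same plots with the same yields.  Column names are suffixed
    with their stage.  This is the concatenated-feature baseline against
    which entropy-weight fusion is compared.
    """
    if not feature_tables:
        raise ValidationError("no feature tables given")
    stages = list(feature_tables)
    first = feature_tables[stages[0]]
    blocks = []
    for stage in stages:
        t = feature_tables[stage]
        if list(t.X.index) != list(first.X.index):
            raise ValidationError(f"plot ids of stage {stage!r} do not match")
        if not np.allclose(t.y.to_numpy(), first.y.to_numpy()):
            raise ValidationError(f"yields of stage {stage!r} do not match")
        blocks.append(t.X.add_suffix(f"_{stage}"))
    X = pd.concat(blocks, axis=1)
    combined = FeatureTable(label or "+".join(stages), X, first.y.copy())
    return nested_cv(combined, grid, cv_config)
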