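"""Accuracy metrics, metric-distribution summaries and paired tests.

R^2 = 1 - SSres/SStot, RMSE, RRMSE = RMSE / mean(y) * 100 (%), MAE; plus the
distribution summaries used to report repeated-CV results, the pairwise
coefficient-of-determination matrix between per-plot stage predictions, and
the paired t-test used to compare fold-level metric series between models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "MetricSet",
    "regression_metrics",
    "metric_distribution",
    "paired_metric_test",
    "PairedTestResult",
    "interstage_regression",
]


@dataclass(frozen=True)
class MetricSet:
    """The four test metrics for one evaluation: R^2, RMSE, RRMSE (%), MAE."""

    r2: float
    rmse: float
    rrmse: float
    mae: float
    n: int


def regression_metrics(y_true, y_pred):
    """Compute the standard four regression metrics.

    Requires >= 2 samples, a non-constant ``y_true`` (else R^2 is undefined)
    and a nonzero mean of ``y_true`` (else RRMSE is undefined).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    n = y_true.size
    if n < 2:
        raise ValidationError("metrics require at least 2 samples")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("R^2 undefined: y_true has zero variance")
    y_bar = float(y_true.mean())
    if y_bar == 0:
        raise ValidationError("RRMSE undefined: mean of y_true is zero")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(ss_res / n))
    return MetricSet(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        rrmse=rmse / y_bar * 100.0,
        mae=float(np.mean(np.abs(y_true - y_pred))),
        n=n,
    )


def metric_distribution(fold_metrics):
    """Summarize per-fold metrics over a repeated-CV run.

    Accepts a DataFrame with columns among (r2, rmse, rrmse, mae) or a list
    of :class:`MetricSet`.  Returns a DataFrame with one row per metric
    (mean, sd, min, q25, median, q75, max, n); the mean is the headline
    value for a repeated-CV experiment.
    """
    if isinstance(fold_metrics, pd.DataFrame):
        df = fold_metrics
    else:
        df = pd.DataFrame([vars(m) for m in fold_metrics])
    cols = [c for c in ("r2", "rmse", "rrmse", "mae") if c in df.columns]
    if df.empty or not cols:
        raise ValidationError("no fold metrics to summarize")
    rows = {}
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        rows[c] = {
            "mean": v.mean(),
            "sd": v.std(ddof=1) if v.size > 1 else 0.0,
            "min": v.min(),
            "q25": np.quantile(v, 0.25),
            "median": np.quantile(v, 0.5),
            "q75": np.quantile(v, 0.75),
            "max": v.max(),
            "n": v.size,
        }
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test outcome on fold-paired metric series."""

    t: float
    p: float
    mean_difference: float
    n: int
    degenerate: bool = False

    @property
    def significant(self):
        """Significance at the P <= 0.001 level."""
        return (not self.degenerate) and self.p <= 0.001


def paired_metric_test(metrics_a, metrics_b):
    """Two-sided paired t-test between two fold-paired metric series.

    Pairs must align by (repeat, fold).  A constant difference (zero sd) is
    flagged ``degenerate`` rather than reported as an infinite t.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired test requires equal-length series")
    if a.size < 2:
        raise ValidationError("paired test requires at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        t = 0.0 if np.allclose(d.mean(), 0.0) else np.inf * np.sign(d.mean())
        return PairedTestResult(float(t), float("nan"), float(d.mean()),
                                int(a.size), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(float(t), float(p), float(d.mean()), int(a.size))


def interstage_regression(stage_predictions):
    """Pairwise R^2 matrix between per-plot mean predictions of stages.

    ``stage_predictions`` maps stage -> per-plot prediction Series (already
    averaged over repeats) or -> :class:`~wheatfusion.enr.StagePrediction`
    (averaged here).  Returns a symmetric DataFrame of squared Pearson
    correlations with unit diagonal.
    """
    series = {}
    for stage, obj in stage_predictions.items():
        s = obj.oof_mean() if hasattr(obj, "oof_mean") else pd.Series(obj)
        series[stage] = s
    stages = list(series)
    if not stages:
        raise ValidationError("no stage predictions given")
    base_index = series[stages[0]].index
    for stage in stages[1:]:
        if not series[stage].index.equals(base_index):
            series[stage] = series[stage].reindex(base_index)
            if series[stage].isna().any():
                raise ValidationError(f"stage {stage!r} missing predictions for some plots")
    mat = pd.DataFrame(
        np.eye(len(stages)), index=stages, columns=stages
    )
    for i, si in enumerate(stages):
        for j in range(i + 1, len(stages)):
            sj = stages[j]
            r = np.corrcoef(series[si].to_numpy(), series[sj].to_numpy())[0, 1]
            mat.loc[si, sj] = mat.loc[sj, si] = r**2
    return mat
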