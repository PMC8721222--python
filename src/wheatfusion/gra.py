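"""Gray relational analysis (GRA) feature ranking.

GRA scores how closely each comparison series (an index, observed over the
plots) tracks the reference series (grain yield).  Every series is first made
dimensionless by dividing by its own mean; for feature i the difference
series is Delta_i(k) = |x0(k) - xi(k)|, and the gray relational coefficient

    xi_i(k) = (Dmin + zeta * Dmax) / (Delta_i(k) + zeta * Dmax)

uses the global minimum/maximum of the difference data over *all* features
and samples, with distinguishing coefficient zeta (default 0.5).  The gray
relational degree gamma_i is the sample mean of xi_i(k); features are ranked
by descending gamma.

A per-stage feature count is then chosen by iteratively feeding the top-k
ranked features to the elastic-net training procedure and locating the point
where the inner-CV MAE curve stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enr import CVConfig, grid_search
from .exceptions import NormalizationError, ValidationError
from .indices import FeatureTable

__all__ = [
    "GRAConfig",
    "GRAResult",
    "gray_relational_degree",
    "rank_features",
    "select_feature_count",
    "stable_count",
]


@dataclass(frozen=True)
class GRAConfig:
    """GRA settings; ``zeta`` is the distinguishing coefficient in [0, 1]."""

    zeta: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.zeta <= 1.0:
            raise ValidationError(f"zeta must lie in [0, 1], got {self.zeta}")


@dataclass
class GRAResult:
    """Gray relational degrees with their intermediates.

    ``gamma`` maps feature -> gray relational degree; ``ranks`` maps
    feature -> rank (1 = highest gamma, stable tie-break by input order).
    ``normalized`` holds the mean-normalized series (reference column
    ``__reference__``), ``delta`` the difference series, and
    ``delta_min`` / ``delta_max`` the global extrema.
    """

    gamma: pd.Series
    ranks: pd.Series
    normalized: pd.DataFrame = field(repr=False)
    delta: pd.DataFrame = field(repr=False)
    delta_min: float = 0.0
    delta_max: float = 0.0
    zeta: float = 0.5


def _as_xy(table):
    if isinstance(table, FeatureTable):
        return table.X, table.y
    X, y = table
    return pd.DataFrame(X), pd.Series(np.asarray(y, dtype=float))


def gray_relational_degree(table, config=None):
    """Compute gray relational degrees of all features against the yield.

    ``table`` is a :class:`FeatureTable` (or an ``(X, y)`` pair).  Requires
    at least two samples and no zero-mean series (the mean normalization
    divides by the series mean); a zero-mean series raises
    :class:`NormalizationError` naming it.  If every difference vanishes
    (all features proportional to the reference) all gammas are 1.
    """
    config = config or GRAConfig()
    X, y = _as_xy(table)
    if len(y) < 2:
        raise ValidationError("GRA requires at least 2 samples")
    if len(X.columns) == 0:
        raise ValidationError("GRA requires at least one comparison series")

    ref_mean = y.mean()
    if ref_mean == 0:
        raise NormalizationError("reference series has zero mean", series="reference")
    zero_mean = X.columns[X.mean() == 0].tolist()
    if zero_mean:
        raise NormalizationError(
            f"zero-mean comparison series: {zero_mean}", series=zero_mean
        )

    x0 = y.to_numpy() / ref_mean
    xi = X.to_numpy() / X.mean().to_numpy()
    delta = np.abs(xi - x0[:, None])
    dmin, dmax = float(delta.min()), float(delta.max())
    if dmax == 0.0:
        gamma = pd.Series(1.0, index=X.columns)
        coeff = np.ones_like(delta)
    else:
        coeff = (dmin + config.zeta * dmax) / (delta + config.zeta * dmax)
        gamma = pd.Series(coeff.mean(axis=0), index=X.columns)

    order = (-gamma.to_numpy()).argsort(kind="stable")
    ranks = pd.Series(0, index=X.columns, dtype=int)
    ranks.iloc[order] = np.arange(1, len(order) + 1)
    normalized = pd.DataFrame(xi, index=X.index, columns=X.columns)
    normalized["__reference__"] = x0
    return GRAResult(
        gamma=gamma,
        ranks=ranks,
        normalized=normalized,
        delta=pd.DataFrame(delta, index=X.index, columns=X.columns),
        delta_min=dmin,
        delta_max=dmax,
        zeta=config.zeta,
    )


def rank_features(gra_result):
    """Feature names sorted by descending gray relational degree.

    Ties preserve the input (registry) order — a stable, deterministic
    tie-break.
    """
    ranks = gra_result.ranks.sort_values(kind="stable")
    return list(ranks.index)


def select_feature_count(ranked_features, table, grid, cv_config=None, tolerance=0.01):
    """Choose how many top-ranked features to keep (iterative-addition curve).

    For k = 1..m the elastic-net training procedure (inner-CV grid search)
    is run on the top-k features and its best mean inner-CV MAE recorded.
    Returns ``(k, curve)`` where k is the smallest count whose MAE is within
    ``tolerance`` (relative) of the curve minimum — the point where the curve
    has "stabilized" — and ``curve`` is a DataFrame (n_features, mae).
    """
    if not ranked_features:
        raise ValidationError("ranked feature list is empty")
    X, y = _as_xy(table)
    cv_config = cv_config or CVConfig()
    maes = []
    for k in range(1, len(ranked_features) + 1):
        cols = list(ranked_features[:k])
        try:
            result = grid_search(X[cols], y, grid, cv_config)
        except Exception as exc:
            raise ValidationError(f"training-curve CV failed at k={k}: {exc}") from exc
        maes.append(result.best_score)
    curve = pd.DataFrame(
        {"n_features": np.arange(1, len(maes) + 1), "mae": maes}
    )
    return stable_count(maes, tolerance), curve


def stable_count(maes, tolerance):
    """Smallest k whose MAE is within ``tolerance`` (relative) of the curve
    minimum — the point where adding features stops paying."""
    maes = list(maes)
    if not maes:
        raise ValidationError("empty MAE curve")
    threshold = min(maes) * (1.0 + tolerance)
    return int(next(i + 1 for i, m in enumerate(maes) if m <= threshold))
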