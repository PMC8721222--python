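"""Model/Results interface over the stage regression and fusion machinery.

Two estimators in the statsmodels idiom: construct a model object from data,
call ``fit()``, and get a Results object carrying estimates, per-fold
uncertainty and a ``summary()`` table.

``StageYieldModel`` — the per-stage elastic net with repeated nested CV.
``EntropyFusionModel`` — the entropy-weight fusion of several stage models.
"""

from __future__ import annotations

import pandas as pd

from . import enr, ewf, gra
from .exceptions import ValidationError
from .indices import FeatureTable, build_feature_table
from .metrics import metric_distribution

__all__ = [
    "StageYieldModel",
    "StageYieldResults",
    "EntropyFusionModel",
    "EntropyFusionResults",
]


def _format_summary(title, blocks):
    width = max(len(title), 58)
    lines = [title.center(width), "=" * width]
    for name, frame in blocks:
        lines.append(name)
        lines.append("-" * width)
        lines.append(frame.to_string())
        lines.append("")
    return "\n".join(lines)


class StageYieldModel:
    """Elastic-net yield model for one growth stage.

    Parameters
    ----------
    feature_table : FeatureTable
        Plots x indices matrix with the measured yield reference.
    grid : HyperGrid, optional
        Hyperparameter candidates (default: the canonical 30x30 lists,
        crossed).
    cv : CVConfig, optional
        Nested-CV protocol (default 10 outer folds x 50 repeats, 10 inner).
    select_features : bool
        If True, rank features by gray relational degree and keep only the
        count at which the training MAE curve stabilizes, before the CV run.
    """

    def __init__(self, feature_table, grid=None, cv=None, select_features=False,
                 gra_config=None, selection_tolerance=0.01):
        self.feature_table = feature_table
        self.grid = grid or enr.default_grid()
        self.cv = cv or enr.CVConfig()
        self.select_features = select_features
        self.gra_config = gra_config or gra.GRAConfig()
        self.selection_tolerance = selection_tolerance

    @classmethod
    def from_dataframe(cls, plot_table, stage, features=None,
                       nrct_grouping="treatment", **kwargs):
        """Build the model straight from the canonical plot table."""
        table = build_feature_table(plot_table, stage, features=features,
                                    nrct_grouping=nrct_grouping)
        return cls(table, **kwargs)

    def fit(self):
        """Run (optional GRA selection and) repeated nested CV."""
        table = self.feature_table
        gra_result, ranked, n_selected, curve = None, None, None, None
        if self.select_features:
            gra_result = gra.gray_relational_degree(table, self.gra_config)
            ranked = gra.rank_features(gra_result)
            n_selected, curve = gra.select_feature_count(
                ranked, table, self.grid, self.cv, self.selection_tolerance
            )
            table = table.subset(ranked[:n_selected])
        prediction = enr.nested_cv(table, self.grid, self.cv)
        return StageYieldResults(self, prediction, gra_result, ranked,
                                 n_selected, curve)


class StageYieldResults:
    """Fitted per-stage results: out-of-fold predictions and fold metrics."""

    def __init__(self, model, prediction, gra_result=None, ranked_features=None,
                 n_selected=None, mae_curve=None):
        self.model = model
        self.prediction = prediction
        self.gra_result = gra_result
        self.ranked_features = ranked_features
        self.n_selected = n_selected
        self.mae_curve = mae_curve

    @property
    def stage(self):
        return self.prediction.stage

    @property
    def fold_metrics(self):
        return self.prediction.fold_metrics

    @property
    def oof_predictions(self):
        """Per-plot prediction averaged over outer repeats."""
        return self.prediction.oof_mean()

    @property
    def metrics(self):
        """Headline (mean over folds) R^2, RMSE, RRMSE, MAE."""
        return self.prediction.mean_metrics()

    def metric_summary(self):
        return metric_distribution(self.fold_metrics)

    def summary(self):
        """Plain-text summary table."""
        blocks = [("Test-phase metric distribution over outer folds",
                   self.metric_summary().round(4))]
        if self.gra_result is not None:
            ranking = pd.DataFrame(
                {"gamma": self.gra_result.gamma, "rank": self.gra_result.ranks}
            ).sort_values("rank")
            blocks.append((f"GRA ranking (selected top {self.n_selected})",
                           ranking.round(4)))
        return _format_summary(
            f"Stage yield model: {self.stage} "
            f"({self.prediction.n_models} outer fits)", blocks,
        )


class EntropyFusionModel:
    """Entropy-weight fusion of per-stage elastic-net predictions.

    ``feature_tables`` maps stage -> :class:`FeatureTable`; ``combination``
    is a :class:`~wheatfusion.ewf.StageCombination` (>= 2 stages).
    """

    def __init__(self, feature_tables, combination, grid=None, cv=None):
        for s, t in feature_tables.items():
            if not isinstance(t, FeatureTable):
                raise ValidationError(f"feature_tables[{s!r}] is not a FeatureTable")
        self.feature_tables = feature_tables
        self.combination = combination
        self.grid = grid or enr.default_grid()
        self.cv = cv or enr.CVConfig()

    def fit(self):
        fused, weights = ewf.ewf_cv(
            self.feature_tables, self.combination, self.grid, self.cv
        )
        return EntropyFusionResults(self, fused, weights)


class EntropyFusionResults:
    """Fitted fusion results: fused predictions, fold metrics, stage weights."""

    def __init__(self, model, fused, weights):
        self.model = model
        self.prediction = fused
        self.weights = weights

    @property
    def label(self):
        return self.prediction.stage

    @property
    def fold_metrics(self):
        return self.prediction.fold_metrics

    @property
    def oof_predictions(self):
        return self.prediction.oof_mean()

    @property
    def metrics(self):
        return self.prediction.mean_metrics()

    def mean_weights(self):
        """Normalized fusion weight per stage, averaged over folds."""
        return self.weights.groupby("stage", sort=False)["w_norm"].mean()

    def metric_summary(self):
        return metric_distribution(self.fold_metrics)

    def summary(self):
        blocks = [
            ("Fused test-phase metric distribution over outer folds",
             self.metric_summary().round(4)),
            ("Mean entropy weights per stage",
             self.weights.groupby("stage", sort=False)[["h", "d", "w_raw", "w_norm"]]
             .mean().round(4)),
        ]
        return _format_summary(
            f"Entropy-weight fusion: {self.label} "
            f"({'+'.join(self.model.combination.stages)})", blocks,
        )
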