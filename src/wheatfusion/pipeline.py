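"""End-to-end pipeline orchestration.

One config (YAML, flat and human-editable) drives: simulate-or-ingest ->
per-stage feature tables -> GRA ranking / feature-count selection ->
per-stage nested-CV elastic net -> concatenated-feature baseline ->
entropy-weight fusion over stage combinations -> reports.  Every output is
plain CSV plus a JSON manifest; identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, enr, ewf, gra, metrics, synthdata
from .exceptions import ValidationError, WheatFusionError
from .indices import build_feature_table
from .io import read_plot_table, write_plot_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("wheatfusion")


@dataclass
class PipelineConfig:
    """Pipeline settings; exactly one of ``input_path`` / ``generator``."""

    input_path: str | None = None
    generator: dict | None = None
    stages: list | None = None          # None = all stages in the table
    zeta: float = 0.5
    selection_tolerance: float = 0.01
    select_features: bool = True
    grid_mode: str = "cartesian"
    lambda2_values: list | None = None
    fraction_values: list | None = None
    outer_folds: int = 10
    outer_repeats: int = 50
    inner_folds: int = 10
    inner_metric: str = "mae"
    combinations: dict | None = None    # label -> stage list; None = canonical 8
    seed: int = 0
    output_dir: str = "wheatfusion_out"

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise ValidationError(
                "config must set exactly one of input_path / generator"
            )

    @classmethod
    def from_dict(cls, d):
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self):
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def hyper_grid(self):
        kwargs = {"mode": self.grid_mode}
        if self.lambda2_values is not None:
            kwargs["lambda2_values"] = tuple(self.lambda2_values)
        if self.fraction_values is not None:
            kwargs["fraction_values"] = tuple(self.fraction_values)
        return enr.HyperGrid(**kwargs)

    def cv_config(self):
        return enr.CVConfig(
            outer_folds=self.outer_folds, outer_repeats=self.outer_repeats,
            inner_folds=self.inner_folds, inner_metric=self.inner_metric,
            seed=self.seed,
        )

    def combination_set(self, available_stages):
        if self.combinations is None:
            combos = [c for c in ewf.DEFAULT_COMBINATIONS
                      if set(c.stages) <= set(available_stages)]
        else:
            combos = [ewf.StageCombination(label, tuple(stages))
                      for label, stages in self.combinations.items()]
        for c in combos:
            missing = set(c.stages) - set(available_stages)
            if missing:
                raise ValidationError(
                    f"combination {c.label!r} references unknown stage(s) {missing}"
                )
        return combos


def _config_hash(config):
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config):
    """Execute the full pipeline; returns the run manifest (also written).

    Aborts on the first failing step, naming it in the partial manifest
    written to the output directory before the error is re-raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "outputs": [],
        "status": "running",
    }

    def emit(name, writer):
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        log.info("wrote %s", path)

    step = "ingest"
    try:
        if config.input_path is not None:
            table = read_plot_table(config.input_path)
        else:
            g = dict(config.generator or {})
            g.setdefault("seed", config.seed)
            table = synthdata.simulate_trial(**g)
            emit("plot_table.csv", lambda p: write_plot_table(table, p))
        stages = config.stages or list(dict.fromkeys(table["stage"]))

        step = "features"
        tables = {}
        for stage in stages:
            tables[stage] = build_feature_table(table, stage)
            emit(f"features_{stage}.csv", tables[stage].to_csv)

        step = "rank"
        grid = config.hyper_grid()
        cv = config.cv_config()
        gra_cfg = gra.GRAConfig(zeta=config.zeta)
        ranking_rows = []
        selected = {}
        for stage in stages:
            result = gra.gray_relational_degree(tables[stage], gra_cfg)
            ranked = gra.rank_features(result)
            for rank, name in enumerate(ranked, start=1):
                ranking_rows.append(
                    {"stage": stage, "rank": rank, "acronym": name,
                     "gamma": result.gamma[name]}
                )
            if config.select_features:
                k, curve = gra.select_feature_count(
                    ranked, tables[stage], grid, cv, config.selection_tolerance
                )
                selected[stage] = ranked[:k]
                emit(f"mae_curve_{stage}.csv",
                     lambda p, c=curve: c.to_csv(p, index=False))
            else:
                selected[stage] = ranked
        import pandas as pd

        emit("gra_ranking.csv",
             lambda p: pd.DataFrame(ranking_rows).to_csv(p, index=False))
        manifest["selected_feature_counts"] = {s: len(v) for s, v in selected.items()}
        cv_tables = {s: tables[s].subset(selected[s]) for s in stages}

        step = "train"
        stage_preds = {}
        for stage in stages:
            pred = enr.nested_cv(cv_tables[stage], grid, cv)
            stage_preds[stage] = pred
            emit(f"predictions_{stage}.csv",
                 lambda p, d=pred: d.predictions.to_csv(p, index=False))
            emit(f"fold_metrics_{stage}.csv",
                 lambda p, d=pred: d.fold_metrics.to_csv(p, index=False))
        if len(stages) >= 2:
            emit("interstage_r2.csv",
                 lambda p: metrics.interstage_regression(stage_preds).to_csv(p))
            concat_pred = enr.concat_stage_cv(cv_tables, grid, cv, label="concat_all")
            emit("predictions_concat_all.csv",
                 lambda p: concat_pred.predictions.to_csv(p, index=False))
            emit("fold_metrics_concat_all.csv",
                 lambda p: concat_pred.fold_metrics.to_csv(p, index=False))

        step = "fuse"
        combos = config.combination_set(stages)
        if combos:
            results, comparison = ewf.evaluate_combinations(cv_tables, combos, grid, cv)
            for label, (fused, weights) in results.items():
                emit(f"predictions_{label}.csv",
                     lambda p, d=fused: d.predictions.to_csv(p, index=False))
                emit(f"fold_metrics_{label}.csv",
                     lambda p, d=fused: d.fold_metrics.to_csv(p, index=False))
                emit(f"weights_{label}.csv",
                     lambda p, w=weights: w.to_csv(p, index=False))
            emit("combinations.csv", lambda p: comparison.to_csv(p))
            manifest["combinations"] = [c.label for c in combos]
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_step"] = step
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        if isinstance(exc, WheatFusionError):
            raise
        raise WheatFusionError(f"pipeline step {step!r} failed: {exc}") from exc

    manifest["status"] = "complete"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
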