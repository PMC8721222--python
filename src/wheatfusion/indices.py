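"""Spectral vegetation indices and normalized relative canopy temperature.

A registry of 21 multispectral vegetation indices (VIs) computed from five
band reflectances (blue, green, red, red-edge, near-IR) plus the normalized
relative canopy temperature (NRCT), and the construction of per-stage
plots x features tables with the measured grain yield as reference vector.

Several index formulae circulate in typographically corrupted forms; the
registry stores the canonical form from each index's original developer and
records in ``IndexDefinition.note`` where a published transcription was
repaired (MSR, RDVI, MTVI2, EVI lost their square roots / constant terms;
OSAVI's soil constant is 0.16).  PSRI, SIPI and MCARI are kept in the exact
variant used by the source protocol even where other variants exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    NormalizationError,
    UndefinedValueError,
    UnknownIndexError,
    ValidationError,
)

__all__ = [
    "IndexDefinition",
    "REGISTRY",
    "multispectral_acronyms",
    "compute_index",
    "compute_nrct",
    "build_feature_table",
    "FeatureTable",
]

_BAND_KEYS = ("blue", "green", "red", "rededge", "nir")


@dataclass(frozen=True)
class IndexDefinition:
    """One registered index: acronym, full name, required inputs, formula."""

    acronym: str
    name: str
    inputs: tuple
    func: object
    note: str = ""


def _sqrt(x):
    with np.errstate(invalid="ignore"):
        return np.sqrt(x)


_FORMULAS = [
    ("CIRE", "Chlorophyll index red-edge", ("nir", "rededge"),
     lambda b: b["nir"] / b["rededge"] - 1.0, ""),
    ("DVI", "Difference vegetation index", ("nir", "red"),
     lambda b: b["nir"] - b["red"], ""),
    ("EVI", "Enhanced vegetation index", ("nir", "red", "blue"),
     lambda b: 2.5 * (b["nir"] - b["red"]) / (b["nir"] + 6.0 * b["red"] - 7.5 * b["blue"] + 1.0),
     "canonical denominator NIR + 6R - 7.5B + 1 restored"),
    ("GNDVI", "Green normalized difference vegetation index", ("nir", "green"),
     lambda b: (b["nir"] - b["green"]) / (b["nir"] + b["green"]), ""),
    ("MCARI", "Modified chlorophyll absorption in reflectance index", ("rededge", "red", "green"),
     lambda b: ((b["rededge"] - b["red"]) - 0.2 * (b["rededge"] - b["green"]))
     * (b["rededge"] / b["red"]), "red-edge variant, as used by the protocol"),
    ("PSRI", "Plant senescence reflectance index", ("red", "blue", "nir"),
     lambda b: (b["red"] - b["blue"]) / b["nir"], "blue variant, as used by the protocol"),
    ("MSR", "Modified simple ratio index", ("nir", "red"),
     lambda b: (b["nir"] / b["red"] - 1.0) / _sqrt(b["nir"] / b["red"] + 1.0),
     "canonical square root restored"),
    ("MTCI", "MERIS terrestrial chlorophyll index", ("nir", "rededge", "red"),
     lambda b: (b["nir"] - b["rededge"]) / (b["rededge"] - b["red"]), ""),
    ("MTVI2", "Modified triangular vegetation index 2", ("nir", "green", "red"),
     lambda b: 1.5 * (1.2 * (b["nir"] - b["green"]) - 2.5 * (b["red"] - b["green"]))
     / _sqrt((2.0 * b["nir"] + 1.0) ** 2 - (6.0 * b["nir"] - 5.0 * _sqrt(b["red"])) - 0.5),
     "canonical square-root denominator restored"),
    ("NDVI", "Normalized difference vegetation index", ("nir", "red"),
     lambda b: (b["nir"] - b["red"]) / (b["nir"] + b["red"]), ""),
    ("NDVIRE", "Normalized difference vegetation index red-edge", ("nir", "rededge"),
     lambda b: (b["nir"] - b["rededge"]) / (b["nir"] + b["rededge"]), ""),
    ("NLI", "Nonlinear vegetation index", ("nir", "red"),
     lambda b: (b["nir"] ** 2 - b["red"]) / (b["nir"] ** 2 + b["red"]), ""),
    ("OSAVI", "Optimized soil-adjusted vegetation index", ("nir", "red"),
     lambda b: 1.16 * (b["nir"] - b["red"]) / (b["nir"] + b["red"] + 0.16),
     "canonical soil constant 0.16 restored"),
    ("PPR", "Plant pigment ratio", ("green", "blue"),
     lambda b: (b["green"] - b["blue"]) / (b["green"] + b["blue"]), ""),
    ("RDVI", "Re-normalized difference vegetation index", ("nir", "red"),
     lambda b: (b["nir"] - b["red"]) / _sqrt(b["nir"] + b["red"]),
     "canonical square root restored"),
    ("RVI", "Ratio vegetation index", ("nir", "red"),
     lambda b: b["nir"] / b["red"], ""),
    ("NRI", "Nitrogen reflectance index", ("green", "red"),
     lambda b: (b["green"] - b["red"]) / (b["green"] + b["red"]), ""),
    ("SAVI", "Soil-adjusted vegetation index", ("nir", "red"),
     lambda b: 1.5 * (b["nir"] - b["red"]) / (b["nir"] + b["red"] + 0.5), ""),
    ("SIPI", "Structure insensitive pigment index", ("nir", "blue"),
     lambda b: (b["nir"] - b["blue"]) / (b["nir"] + b["blue"]),
     "blue normalized-difference variant, as used by the protocol"),
    ("TCARI", "Transformed chlorophyll absorption ratio index", ("rededge", "red", "green"),
     lambda b: 3.0 * ((b["rededge"] - b["red"])
                      - 0.2 * (b["rededge"] - b["green"]) * (b["rededge"] / b["red"])), ""),
    ("TVI", "Triangular vegetation index", ("nir", "green", "red"),
     lambda b: 0.5 * (120.0 * (b["nir"] - b["green"]) - 200.0 * (b["red"] - b["green"])), ""),
]

#: Registry in canonical order: 21 multispectral VIs followed by NRCT.
REGISTRY = {a: IndexDefinition(a, n, i, f, note) for a, n, i, f, note in _FORMULAS}
REGISTRY["NRCT"] = IndexDefinition(
    "NRCT", "Normalized relative canopy temperature", ("temperature",), None,
    "(Ti - Tmin)/(Tmax - Tmin) within a flight group",
)


def multispectral_acronyms():
    """The 21 reflectance-only index acronyms, in registry order."""
    return [a for a, d in REGISTRY.items() if "temperature" not in d.inputs]


def _normalize_band_keys(bands):
    out = {}
    for k, v in bands.items():
        key = k[2:] if k.startswith("r_") else k
        if key not in _BAND_KEYS:
            raise ValidationError(f"unknown band {k!r}; expected one of {_BAND_KEYS}")
        out[key] = v
    return out


def compute_index(acronym, **bands):
    """Evaluate one registered multispectral index.

    Band keywords may be short (``nir=0.5``) or column style (``r_nir=0.5``);
    values must lie in [0, 1].  Raises :class:`UnknownIndexError` for an
    unregistered acronym and :class:`UndefinedValueError` when the formula is
    undefined (zero denominator) for the given inputs.
    """
    if acronym not in REGISTRY:
        raise UnknownIndexError(f"unknown index acronym {acronym!r}")
    definition = REGISTRY[acronym]
    if "temperature" in definition.inputs:
        raise ValidationError("NRCT is computed per group; use compute_nrct")
    b = _normalize_band_keys(bands)
    missing = [k for k in definition.inputs if k not in b]
    if missing:
        raise ValidationError(f"{acronym} requires bands {missing}")
    for k in definition.inputs:
        if not 0.0 <= b[k] <= 1.0:
            raise ValidationError(f"band {k}={b[k]} outside [0, 1]")
    vals = {k: np.float64(v) for k, v in b.items()}
    with np.errstate(divide="ignore", invalid="ignore"):
        value = definition.func(vals)
    if not np.isfinite(value):
        raise UndefinedValueError(
            f"{acronym} undefined for inputs {b}", name=acronym, context=b
        )
    return float(value)


def compute_nrct(temperatures, on_degenerate="raise"):
    """Min-max normalize canopy temperatures within one flight group.

    Returns (Ti - Tmin)/(Tmax - Tmin) per plot, in [0, 1].  A group with
    fewer than two plots or a constant temperature cannot anchor the
    normalization: ``on_degenerate="raise"`` raises
    :class:`NormalizationError`; ``"fill"`` substitutes 0.5 for every plot
    and emits a warning.
    """
    t = np.asarray(temperatures, dtype=float)
    tmin, tmax = t.min() if t.size else np.nan, t.max() if t.size else np.nan
    if t.size < 2 or tmax <= tmin:
        if on_degenerate == "fill":
            warnings.warn(
                "degenerate NRCT group (constant or singleton temperatures); "
                "substituting 0.5", stacklevel=2,
            )
            return np.full(t.shape, 0.5)
        raise NormalizationError(
            f"degenerate NRCT group: n={t.size}, Tmin={tmin}, Tmax={tmax}",
            series="NRCT",
        )
    return (t - tmin) / (tmax - tmin)


@dataclass
class FeatureTable:
    """Plots x indices matrix for one growth stage, with the yield reference.

    ``X`` is a DataFrame indexed by plot_id (feature columns in registry
    order), ``y`` the measured grain yield aligned to the same index.
    """

    stage: str
    X: pd.DataFrame
    y: pd.Series = field(repr=False)

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            raise ValidationError("feature matrix and yield vector are misaligned")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValidationError(f"missing cells in feature columns {bad}")

    @property
    def plot_ids(self):
        return list(self.X.index)

    @property
    def feature_names(self):
        return list(self.X.columns)

    def subset(self, features):
        """A new table restricted to the given feature columns (kept order)."""
        return FeatureTable(self.stage, self.X[list(features)].copy(), self.y.copy())

    def to_csv(self, path):
        out = self.X.copy()
        out.insert(0, "plot_id", out.index)
        out["grain_yield_t_ha"] = self.y
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stage):
        df = pd.read_csv(path).set_index("plot_id")
        y = df.pop("grain_yield_t_ha")
        return cls(stage, df, y)


def build_feature_table(plot_table, stage, features=None, nrct_grouping="treatment"):
    """Compute the per-stage feature table from the canonical plot table.

    Parameters
    ----------
    plot_table : DataFrame
        Canonical tidy table (one row per plot x stage; see
        :mod:`wheatfusion.io`).
    stage : str
        Growth-stage label to extract.
    features : sequence of str, optional
        Acronyms to compute (default: full registry, 21 VIs + NRCT).
    nrct_grouping : {"treatment", "stage"}
        NRCT min/max anchor group: one thermal flight per treatment per stage
        (default), or a single stage-wide group.

    Raises an error listing plot ids when any index is non-finite.  Degenerate
    NRCT groups (constant temperatures, or a single plot) fall back to 0.5
    with a warning so pathological inputs do not stall the pipeline.
    """
    features = list(features) if features is not None else list(REGISTRY)
    rows = plot_table[plot_table["stage"] == stage]
    if rows.empty:
        raise ValidationError(f"no observations for stage {stage!r}")
    if rows["plot_id"].duplicated().any():
        dups = rows.loc[rows["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValidationError(f"duplicate observations for plots {dups} at {stage}")
    rows = rows.set_index("plot_id")
    if rows["grain_yield_t_ha"].isna().any():
        missing = rows.index[rows["grain_yield_t_ha"].isna()].tolist()
        raise ValidationError(f"missing yields for plots {missing}")

    bands = {k: rows[f"r_{k}"].to_numpy(dtype=float) for k in _BAND_KEYS}
    data = {}
    for acronym in features:
        if acronym not in REGISTRY:
            raise UnknownIndexError(f"unknown index acronym {acronym!r}")
        definition = REGISTRY[acronym]
        if "temperature" in definition.inputs:
            vals = np.empty(len(rows))
            if nrct_grouping == "treatment":
                groups = rows.groupby("treatment_id", sort=False).indices.values()
            elif nrct_grouping == "stage":
                groups = [np.arange(len(rows))]
            else:
                raise ValidationError(f"unknown nrct_grouping {nrct_grouping!r}")
            temps = rows["temperature_c"].to_numpy(dtype=float)
            for idx in groups:
                vals[idx] = compute_nrct(temps[idx], on_degenerate="fill")
            data[acronym] = vals
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = definition.func(bands)
        if not np.all(np.isfinite(vals)):
            bad = rows.index[~np.isfinite(vals)].tolist()
            raise UndefinedValueError(
                f"index {acronym} non-finite for plots {bad} at stage {stage}",
                name=acronym, context=bad,
            )
        data[acronym] = vals
    X = pd.DataFrame(data, index=rows.index)
    return FeatureTable(stage, X, rows["grain_yield_t_ha"].astype(float))
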