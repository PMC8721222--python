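"""Reading and writing the canonical plot table.

The canonical table is a tidy CSV with one row per plot x growth stage:
plot metadata, five band reflectances in [0, 1], canopy temperature (deg C),
and the measured grain yield (t/ha).
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ValidationError

PLOT_TABLE_COLUMNS = [
    "plot_id", "genotype_id", "treatment_id", "replicate_id", "stage",
    "r_blue", "r_green", "r_red", "r_rededge", "r_nir",
    "temperature_c", "grain_yield_t_ha",
]

_REFLECTANCE_COLUMNS = ["r_blue", "r_green", "r_red", "r_rededge", "r_nir"]


def validate_plot_table(df):
    """Validate a plot table in memory; returns the (typed) table.

    Raises :class:`ValidationError` listing offending rows for range or
    uniqueness violations.
    """
    missing = [c for c in PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plot table missing columns: {missing}")
    df = df[PLOT_TABLE_COLUMNS].copy()
    for c in _REFLECTANCE_COLUMNS + ["temperature_c", "grain_yield_t_ha"]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[_REFLECTANCE_COLUMNS + ["temperature_c", "grain_yield_t_ha"]].isna().any(axis=1)
    if bad.any():
        raise ValidationError(
            f"non-numeric or missing values in rows {list(df.index[bad])}",
            rows=df.index[bad],
        )
    refl = df[_REFLECTANCE_COLUMNS]
    out_of_range = ((refl < 0) | (refl > 1)).any(axis=1)
    if out_of_range.any():
        raise ValidationError(
            f"reflectance outside [0, 1] in rows {list(df.index[out_of_range])}",
            rows=df.index[out_of_range],
        )
    nonpos = df["grain_yield_t_ha"] <= 0
    if nonpos.any():
        raise ValidationError(
            f"non-positive grain yield in rows {list(df.index[nonpos])}",
            rows=df.index[nonpos],
        )
    dup = df.duplicated(subset=["plot_id", "stage"], keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicated (plot_id, stage) in rows {list(df.index[dup])}",
            rows=df.index[dup],
        )
    return df


def read_plot_table(path):
    """Read and validate the canonical plot table CSV."""
    return validate_plot_table(pd.read_csv(path))


def write_plot_table(df, path):
    """Write the canonical plot table CSV (validates first)."""
    validate_plot_table(df).to_csv(path, index=False)
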