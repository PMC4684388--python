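"""Canonical tree-level data table and column conventions.

A dataset is a pandas DataFrame with one row per destructively sampled
tree and the columns below.  Carbon stocks are never stored: they are
derived on demand as biomass × carbon concentration, component-wise, so
the two can never disagree.

Columns
-------
tree_id, plot_id : identifiers
D_cm             : diameter at breast height (cm)
H_m              : total tree height (m)
biomass_{c}_kg   : oven-dry biomass of component c in
                   {stem, branch, foliage, root} (kg)
cc_{c}           : carbon concentration (mass fraction in (0, 1)) of c
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .allometry import COMPONENTS, Response

__all__ = [
    "REQUIRED_COLUMNS",
    "BIOMASS_COLUMNS",
    "CONCENTRATION_COLUMNS",
    "validate_tree_table",
    "biomass_matrix",
    "concentration_matrix",
    "carbon_matrix",
    "response_matrix",
    "total_biomass",
    "total_carbon",
]

BIOMASS_COLUMNS = tuple(f"biomass_{c}_kg" for c in COMPONENTS)
CONCENTRATION_COLUMNS = tuple(f"cc_{c}" for c in COMPONENTS)
REQUIRED_COLUMNS = ("tree_id", "plot_id", "D_cm", "H_m") + BIOMASS_COLUMNS + CONCENTRATION_COLUMNS


class SchemaError(ValueError):
    """Raised when a tree table is missing columns or fails row validation."""


def validate_tree_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tree table against the canonical schema.

    Checks column presence, numeric types, positivity of D and H,
    non-negative biomass and concentrations in (0, 1).  Returns the
    frame (unchanged) on success; raises :class:`SchemaError` naming
    the offending columns or rows otherwise.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tree table is missing required columns: {', '.join(missing)}")
    numeric = ("D_cm", "H_m") + BIOMASS_COLUMNS + CONCENTRATION_COLUMNS
    bad_rows = []
    values = df[list(numeric)].apply(pd.to_numeric, errors="coerce")
    for idx in df.index[values.isna().any(axis=1)]:
        bad_rows.append(f"row {idx}: non-numeric value")
    ok = values.dropna()
    for idx in ok.index:
        row = ok.loc[idx]
        if row["D_cm"] <= 0 or row["H_m"] <= 0:
            bad_rows.append(f"row {idx}: D_cm and H_m must be positive")
        elif (row[list(BIOMASS_COLUMNS)] < 0).any():
            bad_rows.append(f"row {idx}: negative biomass")
        elif not ((row[list(CONCENTRATION_COLUMNS)] > 0) & (row[list(CONCENTRATION_COLUMNS)] < 1)).all():
            bad_rows.append(f"row {idx}: carbon concentrations must lie in (0, 1)")
    if bad_rows:
        raise SchemaError("; ".join(bad_rows))
    return df


def biomass_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 4) biomass array in component order stem, branch, foliage, root."""
    return df[list(BIOMASS_COLUMNS)].to_numpy(dtype=float)


def concentration_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 4) carbon-concentration array in component order."""
    return df[list(CONCENTRATION_COLUMNS)].to_numpy(dtype=float)


def carbon_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 4) carbon stock (kg C) = biomass × concentration, component-wise."""
    return biomass_matrix(df) * concentration_matrix(df)


def response_matrix(df: pd.DataFrame, response: Response) -> np.ndarray:
    """Observed (n, 4) response for a model: biomass or derived carbon."""
    response = Response(response)
    if response is Response.BIOMASS:
        return biomass_matrix(df)
    return carbon_matrix(df)


def total_biomass(df: pd.DataFrame) -> np.ndarray:
    return biomass_matrix(df).sum(axis=1)


def total_carbon(df: pd.DataFrame) -> np.ndarray:
    return carbon_matrix(df).sum(axis=1)
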