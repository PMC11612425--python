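"""Cell tables: per-cell centroid records linking images, graphs and statistics.

A cell table is a pandas DataFrame with columns
``cell_id, x, y, sample_id, condition, cell_type`` where ``x`` is the column
index and ``y`` the row index of the centroid (0-based pixel centers).
``cell_type`` may be missing (NaN / empty) before typing has run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["cell_id", "x", "y", "sample_id", "condition"]
ALL_COLUMNS = REQUIRED_COLUMNS + ["cell_type"]


class CellTableError(ValueError):
    """Raised when a cell table violates its schema or invariants."""


def validate_cell_table(df: pd.DataFrame, image_shape: tuple[int, int] | None = None) -> pd.DataFrame:
    """Validate a cell table and return a normalized copy.

    Checks: required columns, finite coordinates, cell_id uniqueness within
    each sample, and a single condition label per sample.  If *image_shape*
    (rows, cols) is given, coordinates must fall inside it.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CellTableError(f"cell table is missing required columns: {missing}")
    out = df.copy()
    if "cell_type" not in out.columns:
        out["cell_type"] = np.nan
    out["x"] = pd.to_numeric(out["x"], errors="raise")
    out["y"] = pd.to_numeric(out["y"], errors="raise")
    bad = out.loc[~np.isfinite(out["x"]) | ~np.isfinite(out["y"])]
    if len(bad):
        raise CellTableError(f"non-finite coordinates for cells: {bad['cell_id'].tolist()[:5]}")
    dup = out.duplicated(subset=["sample_id", "cell_id"], keep=False)
    if dup.any():
        offenders = out.loc[dup, ["sample_id", "cell_id"]].drop_duplicates()
        raise CellTableError(f"duplicate cell_id within sample: {offenders.values.tolist()[:5]}")
    ncond = out.groupby("sample_id")["condition"].nunique()
    mixed = ncond[ncond > 1]
    if len(mixed):
        raise CellTableError(f"samples with more than one condition label: {list(mixed.index)}")
    if image_shape is not None:
        rows, cols = image_shape
        outside = out.loc[(out["x"] < 0) | (out["x"] >= cols) | (out["y"] < 0) | (out["y"] >= rows)]
        if len(outside):
            raise CellTableError(
                f"cells outside image bounds {image_shape}: {outside['cell_id'].tolist()[:5]}"
            )
    return out


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table CSV (header cell_id,x,y,sample_id,condition,cell_type)."""
    df = pd.read_csv(path)
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path) -> None:
    validate_cell_table(df)[ALL_COLUMNS].to_csv(path, index=False)


def sample_cells(df: pd.DataFrame, sample_id) -> pd.DataFrame:
    """Rows of one sample, in stable cell_id-sorted order."""
    sub = df.loc[df["sample_id"] == sample_id]
    if not len(sub):
        raise CellTableError(f"sample {sample_id!r} not present in cell table")
    return sub.sort_values("cell_id", kind="stable").reset_index(drop=True)
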