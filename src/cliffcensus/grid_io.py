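"""Grid-cell census data model and CSV readers/writers.

A cliff wall is photographed, rectified and overlaid with a square grid
(10 m x 10 m cells by default); each cell receives an integer count of
"visual units" -- the plant units distinguishable through the telescope.
Partial cells at the image borders are flagged ``included = False`` to
avoid the edge effect; they keep their counts but are ignored by every
downstream analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_, ValidationError

__all__ = ["GridCensus", "load_census", "write_census", "exclude_edge_cells", "total_count"]

_REQUIRED_COLUMNS = ("cell_id", "visual_units")


@dataclass(frozen=True)
class GridCensus:
    """Per-cell visual-unit counts for one cliff wall.

    Parameters
    ----------
    cells
        DataFrame with columns ``cell_id`` (unique identifiers),
        ``visual_units`` (non-negative integers) and ``included``
        (booleans). An optional ``rock_fraction`` column (fraction of the
        cell covered by rock in the photograph) may be present.
    cell_size_m
        Side length of a grid cell in metres (metadata only).
    wall_area_m2
        Approximate wall area in square metres (metadata only).
    """

    cells: pd.DataFrame
    cell_size_m: float = 10.0
    wall_area_m2: Optional[float] = None

    def __post_init__(self) -> None:
        df = self.cells
        for col in _REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"census table is missing required column {col!r}")
        if "included" not in df.columns:
            df = df.assign(included=True)
        counts = df["visual_units"]
        nonint = counts[(counts != np.floor(counts)) | counts.isna()]
        if len(nonint):
            bad = df.loc[nonint.index[0], "cell_id"]
            raise ValidationError(f"cell {bad!r} has a non-integer visual-unit count")
        if (counts < 0).any():
            bad = df.loc[counts.lt(0).idxmax(), "cell_id"]
            raise ValidationError(f"cell {bad!r} has a negative visual-unit count")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValidationError(f"duplicate cell id {dup!r}")
        if self.cell_size_m <= 0:
            raise ValidationError("cell_size_m must be positive")
        if self.wall_area_m2 is not None and self.wall_area_m2 <= 0:
            raise ValidationError("wall_area_m2 must be positive")
        df = df.assign(
            visual_units=counts.astype(np.int64),
            included=df["included"].astype(bool),
        ).reset_index(drop=True)
        object.__setattr__(self, "cells", df)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_included(self) -> int:
        return int(self.cells["included"].sum())

    @property
    def included_counts(self) -> np.ndarray:
        """Visual-unit counts of the included cells, in row order."""
        return self.cells.loc[self.cells["included"], "visual_units"].to_numpy()

    def summary(self) -> dict:
        counts = self.included_counts
        return {
            "n_cells": self.n_cells,
            "n_included": self.n_included,
            "total_visual_units": int(counts.sum()),
            "mean_per_cell": float(counts.mean()) if len(counts) else 0.0,
            "max_per_cell": int(counts.max()) if len(counts) else 0,
            "cell_size_m": self.cell_size_m,
            "wall_area_m2": self.wall_area_m2,
        }

    def write_summary(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def load_census(
    path: Union[str, Path],
    *,
    cell_size_m: float = 10.0,
    wall_area_m2: Optional[float] = None,
    rock_fraction_threshold: Optional[float] = None,
) -> GridCensus:
    """Read a census table from CSV.

    Expected header: ``cell_id,visual_units[,included][,rock_fraction]``.
    ``included`` defaults to true for every row. If
    ``rock_fraction_threshold`` is given and a ``rock_fraction`` column is
    present, cells whose rock fraction falls below the threshold are
    additionally flagged as excluded (a convenience for edge-cell removal;
    off by default -- edge cells are normally excluded by an explicit id
    list, see :func:`exclude_edge_cells`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "included" not in df.columns:
        df["included"] = True
    else:
        df["included"] = df["included"].map(_parse_bool)
    if rock_fraction_threshold is not None:
        if "rock_fraction" not in df.columns:
            raise FormatError(f"{path}: rock_fraction_threshold given but no rock_fraction column")
        df.loc[df["rock_fraction"] < rock_fraction_threshold, "included"] = False
    return GridCensus(df, cell_size_m=cell_size_m, wall_area_m2=wall_area_m2)


def write_census(census: GridCensus, path: Union[str, Path]) -> None:
    """Write the census back to CSV (round-trips counts and flags exactly)."""
    census.cells.to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "t", "yes", "y", "1"}:
        return True
    if text in {"false", "f", "no", "n", "0"}:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean included flag")


def exclude_edge_cells(census: GridCensus, cell_ids: Iterable[str]) -> GridCensus:
    """Return a census with the listed cells flagged as excluded.

    Counts are untouched and the operation is idempotent. Unknown ids
    raise a lookup error.
    """
    ids = list(cell_ids)
    known = set(census.cells["cell_id"])
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise LookupError_(f"unknown cell id(s): {unknown}")
    df = census.cells.copy()
    df.loc[df["cell_id"].isin(ids), "included"] = False
    return replace(census, cells=df)


def total_count(census: GridCensus, cf: Optional["CorrectionFactor"] = None) -> float:
    """Sum of visual units over included cells, optionally CF-corrected.

    With a correction factor, each cell's count is multiplied by the CF
    mean before summing, converting visual units into estimated
    individuals.
    """
    raw = float(census.included_counts.sum())
    if cf is None:
        return raw
    return raw * cf.mean_ratio
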