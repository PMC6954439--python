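"""Per-cell and per-group morphology statistics and CSV export.

Each cell is summarised by the count and percentage of objects in each of
the four classes, plus the per-object (extension, area) records of its
filaments and rods. Percentages are count-based (fraction of retained
objects); area-weighted percentages are also written as extra columns
because the choice of denominator is a reporting convention. Groups of
cells (e.g. clones of a cell line) are aggregated by the unweighted mean
of per-cell percentages — cell-level, not object-pooled, averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import MorphClass
from .morphometry import ObjectFeatures

logger = logging.getLogger(__name__)

CLASS_ORDER = (MorphClass.FILAMENT, MorphClass.ROD, MorphClass.PUNCTUM, MorphClass.SWOLLEN)


@dataclass(frozen=True)
class CellSummary:
    """Morphology statistics of one cell."""

    cell_id: str
    n_objects: int
    counts: dict  # MorphClass -> int
    percentages: dict | None  # MorphClass -> float (count-based); None if no objects
    area_percentages: dict | None  # MorphClass -> float (area-weighted)
    filament_records: list  # [(E μm, A μm²), ...]
    rod_records: list

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_objects:
            raise ValueError("class counts must sum to n_objects")
        if self.n_objects > 0:
            assert self.percentages is not None
            total = sum(self.percentages.values())
            if abs(total - 100.0) > 1e-9:
                raise ValueError(f"percentages must sum to 100, got {total}")
        elif self.percentages is not None:
            raise ValueError("empty cell must have undefined (None) percentages")


@dataclass(frozen=True)
class BatchSummary:
    """Group-level means and dispersions of per-cell class percentages."""

    table: pd.DataFrame  # index: group; columns: <class>_pct_mean/_sd, n_cells
    excluded_cells: tuple  # cell_ids excluded for having no objects


def summarize_cell(
    classified: Sequence[tuple[int, MorphClass, ObjectFeatures]],
    cell_id: str,
) -> CellSummary:
    """Count-based class percentages and filament/rod (E, A) records.

    A cell with zero retained objects gets undefined (None) percentages
    rather than zeros, so that empty cells cannot dilute group averages.
    """
    counts = {cls: 0 for cls in CLASS_ORDER}
    areas = {cls: 0.0 for cls in CLASS_ORDER}
    filament_records, rod_records = [], []
    for _, cls, f in classified:
        counts[cls] += 1
        areas[cls] += f.A
        if cls is MorphClass.FILAMENT:
            filament_records.append((f.E, f.A))
        elif cls is MorphClass.ROD:
            rod_records.append((f.E, f.A))
    n = len(classified)
    if n == 0:
        return CellSummary(cell_id, 0, counts, None, None, [], [])
    pct = {cls: 100.0 * counts[cls] / n for cls in CLASS_ORDER}
    total_area = sum(areas.values())
    apct = {cls: 100.0 * areas[cls] / total_area for cls in CLASS_ORDER}
    return CellSummary(cell_id, n, counts, pct, apct, filament_records, rod_records)


def aggregate_cells(
    summaries: Sequence[CellSummary],
    group_of: Mapping[str, str],
) -> BatchSummary:
    """Unweighted per-group mean ± sd of per-cell class percentages.

    Cells with no objects are excluded (and logged); a group left with no
    cells is omitted with a warning. Single-cell groups report sd = 0.
    """
    excluded = tuple(s.cell_id for s in summaries if s.n_objects == 0)
    for cid in excluded:
        logger.warning("cell %s has no retained objects; excluded from group averages", cid)
    rows = []
    for s in summaries:
        if s.n_objects == 0:
            continue
        if s.cell_id not in group_of:
            raise KeyError(f"cell {s.cell_id!r} has no group assignment")
        row = {"group": group_of[s.cell_id], "cell_id": s.cell_id}
        for cls in CLASS_ORDER:
            row[f"{cls.value}_pct"] = s.percentages[cls]
        rows.append(row)
    if not rows:
        warnings.warn("no non-empty cells to aggregate; empty batch summary")
        return BatchSummary(pd.DataFrame(), excluded)
    df = pd.DataFrame(rows)
    surviving_groups = set(df["group"])
    for cid in excluded:
        grp = group_of.get(cid)
        if grp is not None and grp not in surviving_groups:
            warnings.warn(f"group {grp!r} has no cells with objects; omitted")
    pieces = {}
    for cls in CLASS_ORDER:
        col = f"{cls.value}_pct"
        grp = df.groupby("group")[col]
        pieces[f"{col}_mean"] = grp.mean()
        pieces[f"{col}_sd"] = grp.std(ddof=1).fillna(0.0)
    out = pd.DataFrame(pieces)
    out["n_cells"] = df.groupby("group")["cell_id"].count()
    return BatchSummary(out, excluded)


# ---------------------------------------------------------------------------
# CSV export


def objects_table(
    per_cell: Mapping[str, Sequence[tuple[int, MorphClass, ObjectFeatures]]],
) -> pd.DataFrame:
    rows = []
    for cell_id, classified in per_cell.items():
        for label, cls, f in classified:
            rows.append({
                "cell_id": cell_id, "label": label, "class": cls.value,
                "A_um2": f.A, "P_um": f.P, "AR": f.AR, "C": f.C, "S": f.S,
                "MLE_um": f.MLE, "E_um": f.E, "r_eq_um": f.r_eq,
            })
    cols = ["cell_id", "label", "class", "A_um2", "P_um", "AR", "C", "S",
            "MLE_um", "E_um", "r_eq_um"]
    return pd.DataFrame(rows, columns=cols)


def cells_table(summaries: Sequence[CellSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"cell_id": s.cell_id, "n_objects": s.n_objects}
        for cls in CLASS_ORDER:
            row[f"n_{cls.value}"] = s.counts[cls]
        for cls in CLASS_ORDER:
            row[f"{cls.value}_pct"] = s.percentages[cls] if s.percentages else np.nan
        for cls in CLASS_ORDER:
            row[f"{cls.value}_area_pct"] = s.area_percentages[cls] if s.area_percentages else np.nan
        row["filament_E_um"] = ";".join(f"{e:.6g}" for e, _ in s.filament_records)
        row["filament_A_um2"] = ";".join(f"{a:.6g}" for _, a in s.filament_records)
        row["rod_E_um"] = ";".join(f"{e:.6g}" for e, _ in s.rod_records)
        row["rod_A_um2"] = ";".join(f"{a:.6g}" for _, a in s.rod_records)
        rows.append(row)
    return pd.DataFrame(rows)


_HEADERS = {
    "objects": "# one row per segmented object; lengths in um, areas in um^2; "
               "class in {filament,rod,punctum,swollen}\n",
    "cells": "# one row per cell; *_pct are count-based class percentages, "
             "*_area_pct area-weighted; record lists are ';'-separated\n",
    "groups": "# one row per group; unweighted mean/sd over member cells of "
              "count-based class percentages\n",
}


def write_csv(df: pd.DataFrame, path, kind: str, index: bool = False) -> None:
    """Write a table with a leading '#' comment line documenting units."""
    with open(path, "w", newline="") as fh:
        fh.write(_HEADERS[kind])
        df.to_csv(fh, index=index, float_format="%.10g", lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
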