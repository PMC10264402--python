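"""Quality-control filtering of segmented cells and region cropping.

Cells produced by probabilistic segmentation carry summary statistics —
transcript count, elongation (major/minor axis ratio), area and the mean
per-molecule segmentation confidence — that are screened with per-protocol
thresholds before any cell-type matching.  The four imaging-protocol presets
ship with the package (see :data:`QC_PRESETS`); note the deliberate mix of
open and closed boundaries, which is preserved exactly:

    retained  iff  n_transcripts >= min_transcripts
              and  elongation     < max_elongation
              and  area_min      <= area < area_max
              and  avg_confidence > min_avg_confidence
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .io import STAT_COLUMNS, CellTable


@dataclass(frozen=True)
class QCThresholds:
    """Per-protocol cell-level QC thresholds.

    Boundary conventions (inclusive/exclusive) follow the retention rule in
    the module docstring: ``min_transcripts`` inclusive, ``max_elongation``
    exclusive, area half-open ``[area_min, area_max)``, ``min_avg_confidence``
    a strict lower bound.
    """

    min_transcripts: int
    max_elongation: float
    area_min: float
    area_max: float
    min_avg_confidence: float

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be below area_max")
        if not 0.0 <= self.min_avg_confidence < 1.0:
            raise ValueError("min_avg_confidence must lie in [0, 1)")


#: Published per-protocol presets for the four imaging protocols.
QC_PRESETS: dict[str, QCThresholds] = {
    "merfish": QCThresholds(50, 9.0, 2000.0, 45_000.0, 0.86),
    "smfish": QCThresholds(50, 8.0, 500.0, 40_000.0, 0.95),
    "baristaseq": QCThresholds(20, 8.0, 10.0, 300.0, 0.95),
    "exseq": QCThresholds(20, 10.0, 5000.0, 1_500_000.0, 0.8),
}


def retention_mask(stats: pd.DataFrame, thr: QCThresholds) -> pd.Series:
    """Boolean per-cell retention under ``thr`` (vectorized rule)."""
    return (
        (stats["n_transcripts"] >= thr.min_transcripts)
        & (stats["elongation"] < thr.max_elongation)
        & (stats["area"] >= thr.area_min)
        & (stats["area"] < thr.area_max)
        & (stats["avg_confidence"] > thr.min_avg_confidence)
    )


def filter_cells(
    cells: CellTable, thr: QCThresholds
) -> tuple[CellTable, dict[str, int]]:
    """Apply the QC rule; return survivors and per-rule removal counts.

    A removed cell is counted under every rule it violates, so the counts
    may sum to more than the number of removed cells.
    """
    stats = cells.stats
    for col in STAT_COLUMNS:
        if col not in stats.columns:
            raise ValueError(f"missing stat column {col!r}")
        bad = stats[col].isna()
        if bad.any():
            cell = stats.index[bad][0]
            raise ValueError(f"missing stat {col!r} for cell {cell!r}")
    removed = {
        "n_transcripts": int((stats["n_transcripts"] < thr.min_transcripts).sum()),
        "elongation": int((stats["elongation"] >= thr.max_elongation).sum()),
        "area": int(
            ((stats["area"] < thr.area_min) | (stats["area"] >= thr.area_max)).sum()
        ),
        "avg_confidence": int(
            (stats["avg_confidence"] <= thr.min_avg_confidence).sum()
        ),
    }
    keep = retention_mask(stats, thr)
    return cells.subset(stats.index[keep]), removed


def crop_region(cells: CellTable, vertices: np.ndarray) -> CellTable:
    """Retain cells whose centroid lies inside or on a simple polygon.

    The polygon is given as an ordered (k ≥ 3) × 2 vertex array in µm;
    boundary points are retained.  Typical use is cropping to an anatomical
    region of interest whose outline was drawn by hand.
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("polygon needs at least 3 planar vertices")
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("degenerate or self-intersecting polygon")
    stats = cells.stats
    if "x" not in stats.columns or "y" not in stats.columns:
        raise ValueError("cell table has no centroid columns x, y")
    keep = [
        poly.covers(Point(x, y))
        for x, y in zip(stats["x"].to_numpy(), stats["y"].to_numpy())
    ]
    return cells.subset(stats.index[np.asarray(keep, dtype=bool)])


def qc_summary(before: CellTable, after: CellTable) -> dict:
    """Before/after cell counts, retained fraction and surviving gene count."""
    extra = pd.Index(after.cells).difference(pd.Index(before.cells))
    if len(extra):
        raise ValueError("after-table contains cells absent from before-table")
    n_before, n_after = len(before), len(after)
    fraction = n_after / n_before if n_before else 0.0
    if n_after == 0:
        import warnings

        warnings.warn("no cells survived filtering")
    n_genes = int((after.counts.sum(axis=0) > 0).sum()) if n_after else 0
    return {
        "cells_before": n_before,
        "cells_after": n_after,
        "retained_fraction": fraction,
        "genes_detected": n_genes,
    }
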