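"""Cortical-depth summaries of spots, cells and matching results.

Laminar cortex orders neuron subclasses along the axis perpendicular to
the pia, so depth profiles of detected molecules and matched cells are the
main face-validity check for spatial cell typing.  Depth is measured in µm
from the pia, increasing toward white matter, and binned into half-open
intervals ``[k·w, (k+1)·w)`` anchored at depth 0 (default width 25 µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellTable, LabelVector, SpotTable


@dataclass(frozen=True)
class DepthAxis:
    """Half-open depth binning anchored at the pia (depth 0)."""

    bin_width: float = 25.0
    max_depth: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def edges(self, depths: np.ndarray) -> np.ndarray:
        top = self.max_depth if self.max_depth is not None else float(depths.max())
        n_bins = max(1, int(np.floor(top / self.bin_width)) + 1)
        return np.arange(n_bins + 1) * self.bin_width

    def assign(self, depths: np.ndarray) -> np.ndarray:
        """Bin index per depth (half-open bins)."""
        depths = np.asarray(depths, dtype=float)
        if (depths < 0).any():
            raise ValueError("depths must be nonnegative (µm from pia)")
        return np.floor(depths / self.bin_width).astype(int)


def project_depth(
    xy: np.ndarray, pia_point: np.ndarray, wm_point: np.ndarray
) -> np.ndarray:
    """Signed projection of planar points onto a pia→white-matter axis.

    The axis is defined by a point on the pia and a point toward white
    matter; depth is the scalar projection of ``xy − pia_point`` onto the
    unit axis direction, in µm.
    """
    pia = np.asarray(pia_point, dtype=float)
    direction = np.asarray(wm_point, dtype=float) - pia
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("pia and white-matter points coincide")
    return (np.asarray(xy, dtype=float) - pia) @ (direction / norm)


def mean_reads_per_gene(
    cells: CellTable, genes: list[str] | None = None
) -> tuple[pd.Series, float]:
    """Average raw count per gene over the cells that detected it.

    For each gene the mean is taken over cells with count ≥ 1; genes
    detected in no cell are NaN (flagged absent).  The second return value
    is the across-gene average of the defined means — the summary line
    drawn over per-protocol read histograms.
    """
    genes = list(genes) if genes is not None else cells.genes
    if not genes:
        raise ValueError("empty gene subset")
    counts = cells.counts[genes]
    detected = counts > 0
    sums = counts.where(detected).sum(axis=0)
    n_det = detected.sum(axis=0)
    means = sums / n_det.where(n_det > 0)
    overall = float(means.dropna().mean()) if n_det.gt(0).any() else float("nan")
    return means, overall


def _gaussian_kde_1d(
    samples: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Fixed-bandwidth 1-D Gaussian KDE evaluated on a grid, density scale."""
    z = (grid[:, None] - samples[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1)
    dens /= len(samples) * bandwidth * np.sqrt(2.0 * np.pi)
    return dens


@dataclass
class DepthProfile:
    """Per-bin or per-grid-point values along the cortical-depth axis."""

    label: str
    positions: np.ndarray  # bin centers or KDE grid, µm
    values: np.ndarray  # counts, fractions or density
    kind: str  # "density", "fraction" or "count"


def spot_depth_density(
    spots: SpotTable,
    gene_sets: dict[str, list[str]],
    depths: np.ndarray,
    bandwidth: float = 25.0,
    grid_step: float = 5.0,
) -> dict[str, DepthProfile]:
    """Pooled depth density per gene set (e.g. per-layer marker lists).

    ``depths`` supplies the cortical depth of every spot (µm), typically
    from :func:`project_depth`.  All spots of a set's genes are pooled into
    one fixed-bandwidth Gaussian KDE, normalized to integrate to 1 over
    the evaluation grid.
    """
    depths = np.asarray(depths, dtype=float)
    if len(depths) != len(spots):
        raise ValueError("depths must align with the spot table")
    lo = max(0.0, depths.min() - 4 * bandwidth)
    hi = depths.max() + 4 * bandwidth
    grid = np.arange(lo, hi + grid_step, grid_step)
    profiles: dict[str, DepthProfile] = {}
    for label, genes in gene_sets.items():
        mask = spots.genes.isin(genes).to_numpy()
        if not mask.any():
            raise ValueError(f"gene set {label!r} matches no spots")
        dens = _gaussian_kde_1d(depths[mask], grid, bandwidth)
        area = np.trapezoid(dens, grid)
        profiles[label] = DepthProfile(
            label=label, positions=grid, values=dens / area, kind="density"
        )
    return profiles


def matched_depth_profile(
    cells: CellTable,
    labels: LabelVector,
    subclass: str,
    axis: DepthAxis = DepthAxis(),
) -> pd.DataFrame:
    """Per-depth-bin count and fraction of cells matched to one subclass.

    Returns a table with bin center, total cells in the bin, cells matched
    to ``subclass``, and the matched fraction (NaN for empty bins).
    """
    if labels.cells != cells.cells:
        raise ValueError("labels must align with the cell table")
    depths = cells.stats["depth"].to_numpy(dtype=float)
    bins = axis.assign(depths)
    n_bins = bins.max() + 1
    total = np.bincount(bins, minlength=n_bins)
    hit = np.bincount(
        bins, weights=(labels.labels == subclass).astype(float), minlength=n_bins
    )
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, hit / np.where(total > 0, total, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_center": (np.arange(n_bins) + 0.5) * axis.bin_width,
            "n_cells": total,
            "n_matched": hit.astype(int),
            "fraction": frac,
        }
    )


def ensemble_bin_statistics(
    cells: CellTable,
    individual: dict[str, LabelVector],
    combined: dict[str, LabelVector],
    subclass: str,
    axis: DepthAxis = DepthAxis(),
) -> pd.DataFrame:
    """Depth-bin comparison of individual versus combined matchings.

    Per bin the table reports:

    * ``avg_frac`` — arithmetic mean over individual methods of the
      fraction of the bin's cells each method matched to ``subclass``;
    * ``avg_method`` — mean, over cells in the bin, of the number of
      individual methods matching the cell to ``subclass``;
    * ``frac_<name>`` — matched fraction per combined labeling.

    Empty bins carry NaN statistics.
    """
    if not individual or not combined:
        raise ValueError("need at least one individual and one combined labeling")
    depths = cells.stats["depth"].to_numpy(dtype=float)
    bins = axis.assign(depths)
    n_bins = bins.max() + 1
    total = np.bincount(bins, minlength=n_bins).astype(float)
    occupied = total > 0

    def frac_per_bin(lv: LabelVector) -> np.ndarray:
        if lv.cells != cells.cells:
            raise ValueError("labels must align with the cell table")
        hit = np.bincount(
            bins, weights=(lv.labels == subclass).astype(float), minlength=n_bins
        )
        return np.where(occupied, hit / np.where(occupied, total, 1), np.nan)

    method_fracs = np.stack([frac_per_bin(lv) for lv in individual.values()])
    per_cell_votes = np.sum(
        [(lv.labels == subclass).astype(float) for lv in individual.values()], axis=0
    )
    vote_sum = np.bincount(bins, weights=per_cell_votes, minlength=n_bins)
    out = pd.DataFrame(
        {
            "bin_center": (np.arange(n_bins) + 0.5) * axis.bin_width,
            "n_cells": total.astype(int),
            "avg_frac": method_fracs.mean(axis=0),
            "avg_method": np.where(
                occupied, vote_sum / np.where(occupied, total, 1), np.nan
            ),
        }
    )
    for name, lv in combined.items():
        out[f"frac_{name}"] = frac_per_bin(lv)
    return out
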