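"""Correlation-based probabilistic matching of cells to reference subclasses.

Two matchers are provided, both built on Pearson correlation between a
cell's expression vector and per-type reference profiles over the shared
gene set:

* :func:`match_correlation` — correlate each cell against every cluster
  profile and convert the correlation vector ``y`` to probabilities with
  the scaled-correlation transform

      s_i = max(y_i - max(y)/2, 0)**2,   p_i = s_i / sum(s)

  so only types whose correlation exceeds half the best correlation receive
  any mass, and the contrast is sharpened quadratically.

* :func:`match_bootstrap` — repeatedly subsample the shared gene panel,
  assign each cell to its best-correlated profile on the subsample, and
  report the vote fraction over rounds as the confidence.  This captures
  how stable an assignment is under perturbation of the (small) gene panel.

Undefined correlations (constant vectors) are scored 0 rather than NaN, so
degenerate cells flow through and end up unassigned downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .io import CellTable, ConfidenceMatrix, ReferenceProfiles, normalize_counts


@dataclass(frozen=True)
class BootstrapConfig:
    """Gene-subsampling bootstrap settings.

    ``gene_fraction`` of the shared panel (rounded up, minimum 2 genes) is
    drawn without replacement in each of ``rounds`` rounds.
    """

    rounds: int = 100
    gene_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("bootstrap needs at least one round")
        if not 0 < self.gene_fraction <= 1:
            raise ValueError("gene_fraction must lie in (0, 1]")


def cluster_profiles(
    counts: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    statistic: str = "median",
    normalize: bool = False,
    target_libsize: float = 10.0,
    log_transform: bool = False,
    type_order: list[str] | None = None,
) -> ReferenceProfiles:
    """Summarize a labeled reference count matrix into per-type profiles.

    Parameters
    ----------
    counts
        Reference cell × gene counts.
    labels
        Per-cell type label, aligned with ``counts`` rows.
    statistic
        ``"median"`` (robust cluster centroid, the default) or ``"mean"``.
    normalize, target_libsize, log_transform
        Optional per-cell library-size normalization applied before
        summarizing.
    type_order
        Taxonomy order for the output; defaults to sorted label order.
        Every listed type must have at least one cell.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(counts):
        raise ValueError("labels must align with count rows")
    if type_order is None:
        type_order = sorted(set(labels))
    mat = counts.to_numpy(dtype=float)
    if normalize:
        mat = normalize_counts(mat, target_libsize, log_transform)
    rows = []
    for t in type_order:
        member = labels == t
        if not member.any():
            raise ValueError(f"reference type {t!r} has no cells")
        block = mat[member]
        rows.append(np.median(block, axis=0) if statistic == "median" else block.mean(axis=0))
    profiles = pd.DataFrame(rows, index=type_order, columns=counts.columns)
    return ReferenceProfiles(types=list(type_order), profiles=profiles)


def _pearson_rows(cells_mat: np.ndarray, profile_mat: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation, cells × types; zero-variance rows → 0."""
    c = cells_mat - cells_mat.mean(axis=1, keepdims=True)
    p = profile_mat - profile_mat.mean(axis=1, keepdims=True)
    c_norm = np.linalg.norm(c, axis=1)
    p_norm = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (c @ p.T) / np.outer(c_norm, p_norm)
    return np.where(np.isfinite(r), r, 0.0)


def correlate_cell(
    cell: pd.Series | np.ndarray, profiles: ReferenceProfiles
) -> np.ndarray:
    """Pearson correlation of one cell against every type profile.

    The cell vector must already be aligned to the profile gene panel
    (use :func:`shared_genes` / DataFrame reindexing for subsetting).
    Constant vectors yield 0 for every type.
    """
    vec = np.asarray(cell, dtype=float)
    if vec.shape[0] != len(profiles.genes):
        raise ValueError("cell vector length must match profile gene panel")
    if vec.shape[0] < 2:
        raise ValueError("need at least 2 shared genes for correlation")
    return _pearson_rows(vec[None, :], profiles.profiles.to_numpy(dtype=float))[0]


def scaled_probability(y: np.ndarray) -> np.ndarray:
    """Scaled-correlation probabilities from a correlation vector.

    ``s_i = max(y_i - max(y)/2, 0)^2`` normalized to sum 1; if every ``s_i``
    is zero (e.g. no positive correlation) the zero vector is returned,
    which downstream code reads as unassigned.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty correlation vector")
    s = np.maximum(y - y.max() / 2.0, 0.0) ** 2
    total = s.sum()
    return s / total if total > 0 else np.zeros_like(s)


def shared_genes(cells: CellTable, profiles: ReferenceProfiles) -> list[str]:
    """Gene panel shared by the cell table and the reference, in panel order."""
    cell_genes = set(cells.genes)
    return [g for g in profiles.genes if g in cell_genes]


def match_correlation(
    cells: CellTable,
    profiles: ReferenceProfiles,
    normalize: bool = True,
    target_libsize: float = 10.0,
    log_transform: bool = True,
    method_name: str = "correlation",
) -> ConfidenceMatrix:
    """Scaled-correlation matcher: one probability row per cell.

    Both the cells and the profiles are restricted to their shared gene set
    and, by default, library-size normalized and log-transformed before
    correlating; rows sum to 1 or are all-zero (unassignable cell).
    """
    genes = shared_genes(cells, profiles)
    if len(genes) < 2:
        raise ValueError("need at least 2 shared genes between cells and reference")
    cell_mat = cells.counts[genes].to_numpy(dtype=float)
    prof_mat = profiles.profiles[genes].to_numpy(dtype=float)
    if normalize:
        cell_mat = normalize_counts(cell_mat, target_libsize, log_transform)
        prof_mat = normalize_counts(prof_mat, target_libsize, log_transform)
    corr = _pearson_rows(cell_mat, prof_mat)
    scores = np.apply_along_axis(scaled_probability, 1, corr)
    return ConfidenceMatrix(
        cells=cells.cells, types=list(profiles.types), scores=scores,
        method_name=method_name,
    )


def match_bootstrap(
    cells: CellTable,
    profiles: ReferenceProfiles,
    cfg: BootstrapConfig = BootstrapConfig(),
    normalize: bool = True,
    target_libsize: float = 10.0,
    log_transform: bool = True,
    method_name: str = "bootstrap",
) -> ConfidenceMatrix:
    """Gene-subsampling bootstrap matcher: vote fractions per cell and type.

    Each round draws ``ceil(gene_fraction · G)`` of the G shared genes
    without replacement and assigns every cell to its best-correlated type
    (per-round ties broken by taxonomy order).  Confidence is the fraction
    of rounds voting for each type, so rows sum to exactly 1.
    """
    genes = shared_genes(cells, profiles)
    n_sample = max(2, ceil(cfg.gene_fraction * len(genes)))
    if n_sample > len(genes):
        raise ValueError("fewer than 2 shared genes available for sampling")
    cell_mat = cells.counts[genes].to_numpy(dtype=float)
    prof_mat = profiles.profiles[genes].to_numpy(dtype=float)
    if normalize:
        cell_mat = normalize_counts(cell_mat, target_libsize, log_transform)
        prof_mat = normalize_counts(prof_mat, target_libsize, log_transform)
    rng = np.random.default_rng(cfg.seed)
    votes = np.zeros((len(cells), len(profiles.types)))
    for _ in range(cfg.rounds):
        idx = rng.choice(len(genes), size=n_sample, replace=False)
        corr = _pearson_rows(cell_mat[:, idx], prof_mat[:, idx])
        best = corr.argmax(axis=1)  # first max wins: taxonomy-order tie-break
        votes[np.arange(len(cells)), best] += 1.0
    return ConfidenceMatrix(
        cells=cells.cells, types=list(profiles.types), scores=votes / cfg.rounds,
        method_name=method_name,
    )
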