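"""Segmentation-free guided pixel typing from mRNA spot coordinates.

Instead of assigning types to segmented cells, the guided approach rasters
the tissue into a per-gene kernel-density *vector field*: every molecule
contributes an isotropic Gaussian (σ = 2.5 µm by default) to its gene's
channel, evaluated on a µm-scale pixel grid.  Each pixel's gene vector is
then library-size normalized (target 10) and log-transformed, correlated
against per-type signatures built the same way from labeled segmented
cells, and labeled with the best-correlated type when that Pearson
correlation reaches the minimum threshold (default 0.6); pixels below the
threshold or in near-empty background stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    UNASSIGNED,
    CellTable,
    LabelVector,
    ReferenceProfiles,
    SpotTable,
    normalize_counts,
)
from .matcher import _pearson_rows


@dataclass(frozen=True)
class GuidedConfig:
    """Parameters of the guided pixel-typing pipeline.

    ``bandwidth`` is the Gaussian kernel σ in µm; kernels are truncated at
    ``truncate``·σ.  ``density_floor`` excludes background pixels whose
    total raw density (all genes, in molecules) falls below it.
    """

    bandwidth: float = 2.5
    pixel_size: float = 1.0
    target_libsize: float = 10.0
    min_correlation: float = 0.6
    density_floor: float = 1e-3
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.bandwidth <= 0 or self.pixel_size <= 0:
            raise ValueError("bandwidth and pixel size must be positive")
        if not -1.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation must lie in [-1, 1]")


@dataclass
class VectorField:
    """Per-pixel, per-gene KDE density on a regular µm grid.

    ``values`` has shape (height, width, genes); pixel (i, j) is centered
    at ``origin + (j + 0.5, i + 0.5) · pixel_size`` (x right, y down the
    row axis).
    """

    origin: tuple[float, float]
    pixel_size: float
    genes: list[str]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def total_density(self) -> np.ndarray:
        """Per-pixel density summed over genes (molecule units)."""
        return self.values.sum(axis=2)


def kde_field(spots: SpotTable, cfg: GuidedConfig = GuidedConfig()) -> VectorField:
    """Rasterize spots into a per-gene Gaussian KDE vector field.

    Each molecule deposits a 2-D isotropic Gaussian (σ = ``cfg.bandwidth``)
    sampled at pixel centers and truncated at ``cfg.truncate``·σ; with
    µm-scale pixels the sampled kernel mass per molecule is ≈ 1, so the
    field integrates to roughly the number of molecules.
    """
    if len(spots) == 0:
        raise ValueError("empty spot table")
    xy = spots.xy
    pad = cfg.truncate * cfg.bandwidth + cfg.pixel_size
    x0, y0 = xy.min(axis=0) - pad
    x1, y1 = xy.max(axis=0) + pad
    width = int(np.ceil((x1 - x0) / cfg.pixel_size))
    height = int(np.ceil((y1 - y0) / cfg.pixel_size))
    genes = list(spots.panel)
    gene_index = {g: k for k, g in enumerate(genes)}
    values = np.zeros((height, width, len(genes)))

    radius = int(np.ceil(cfg.truncate * cfg.bandwidth / cfg.pixel_size))
    # pixel-center coordinate axes
    xs = x0 + (np.arange(width) + 0.5) * cfg.pixel_size
    ys = y0 + (np.arange(height) + 0.5) * cfg.pixel_size
    norm = cfg.pixel_size**2 / (2.0 * np.pi * cfg.bandwidth**2)
    for (x, y), gene in zip(xy, spots.genes):
        k = gene_index[gene]
        cj = int((x - x0) / cfg.pixel_size)
        ci = int((y - y0) / cfg.pixel_size)
        j_lo, j_hi = max(0, cj - radius), min(width, cj + radius + 1)
        i_lo, i_hi = max(0, ci - radius), min(height, ci + radius + 1)
        gx = np.exp(-0.5 * ((xs[j_lo:j_hi] - x) / cfg.bandwidth) ** 2)
        gy = np.exp(-0.5 * ((ys[i_lo:i_hi] - y) / cfg.bandwidth) ** 2)
        values[i_lo:i_hi, j_lo:j_hi, k] += norm * np.outer(gy, gx)
    return VectorField(
        origin=(float(x0), float(y0)),
        pixel_size=cfg.pixel_size,
        genes=genes,
        values=values,
    )


def signatures_from_labels(
    cells: CellTable,
    labels: LabelVector,
    cfg: GuidedConfig = GuidedConfig(),
) -> ReferenceProfiles:
    """Mean log-normalized expression signature per assigned subclass.

    Every cell is library-size normalized to ``cfg.target_libsize`` and
    log-transformed, then averaged within its label group.  Unassigned
    cells are ignored; a referenced type with no cells is an error.
    """
    if labels.cells != cells.cells:
        raise ValueError("labels must align with the cell table")
    lab = labels.labels
    types = sorted(set(lab) - {UNASSIGNED})
    if not types:
        raise ValueError("no assigned cells to build signatures from")
    mat = normalize_counts(
        cells.counts.to_numpy(dtype=float), cfg.target_libsize, log_transform=True
    )
    rows = []
    for t in types:
        member = lab == t
        if not member.any():
            raise ValueError(f"type {t!r} has no cells")
        rows.append(mat[member].mean(axis=0))
    profiles = pd.DataFrame(rows, index=types, columns=cells.genes)
    return ReferenceProfiles(types=types, profiles=profiles)


@dataclass
class PixelLabelMap:
    """Per-pixel subclass label with the best signature correlation."""

    labels: np.ndarray  # (height, width) object array, UNASSIGNED included
    correlations: np.ndarray  # (height, width) float, NaN where masked
    types: list[str]

    def to_frame(self, field: VectorField) -> pd.DataFrame:
        """Long-format pixel table (x, y in µm, label, correlation)."""
        h, w = self.labels.shape
        ii, jj = np.mgrid[0:h, 0:w]
        x0, y0 = field.origin
        return pd.DataFrame(
            {
                "x": x0 + (jj.ravel() + 0.5) * field.pixel_size,
                "y": y0 + (ii.ravel() + 0.5) * field.pixel_size,
                "label": self.labels.ravel(),
                "correlation": self.correlations.ravel(),
            }
        )


def assign_pixels(
    field: VectorField,
    signatures: ReferenceProfiles,
    cfg: GuidedConfig = GuidedConfig(),
) -> PixelLabelMap:
    """Label every sufficiently dense pixel with its best-correlated type.

    Pixel vectors are normalized exactly like the signatures (library size
    then log1p) and Pearson-correlated against each signature over the
    signature gene panel.  A pixel is labeled with the argmax type when
    that correlation is at least ``cfg.min_correlation``; pixels whose
    total raw density is below ``cfg.density_floor`` or whose best
    correlation falls short stay ``UNASSIGNED``.
    """
    missing = [g for g in signatures.genes if g not in field.genes]
    if missing:
        raise ValueError(f"signature genes absent from field: {missing}")
    cols = [field.genes.index(g) for g in signatures.genes]
    h, w = field.shape
    pixel_mat = field.values[:, :, cols].reshape(h * w, len(cols))
    dense = field.total_density().ravel() >= cfg.density_floor

    labels = np.full(h * w, UNASSIGNED, dtype=object)
    corrs = np.full(h * w, np.nan)
    if dense.any():
        norm_pixels = normalize_counts(
            pixel_mat[dense], cfg.target_libsize, log_transform=True
        )
        sig_mat = signatures.profiles.to_numpy(dtype=float)
        r = _pearson_rows(norm_pixels, sig_mat)
        best = r.argmax(axis=1)
        best_r = r[np.arange(len(best)), best]
        corrs[dense] = best_r
        accept = best_r >= cfg.min_correlation
        idx = np.flatnonzero(dense)[accept]
        labels[idx] = np.asarray(signatures.types, dtype=object)[best[accept]]
    return PixelLabelMap(
        labels=labels.reshape(h, w),
        correlations=corrs.reshape(h, w),
        types=list(signatures.types),
    )
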