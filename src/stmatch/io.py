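"""Data model and file I/O shared by every stage of the matching workflow.

The in-memory containers are thin dataclasses around pandas/numpy objects:

* :class:`SpotTable` — one row per detected mRNA molecule (gene, x, y in µm).
* :class:`CellTable` — cell × gene counts plus per-cell segmentation
  statistics (transcript count, elongation, area, average segmentation
  confidence), centroid and cortical depth.
* :class:`ReferenceProfiles` — ordered subclass taxonomy with a per-type
  expression profile over a gene panel.
* :class:`ConfidenceMatrix` — cell × type matching scores in [0, 1]; the
  unit of exchange between matchers and the ensemble combiners.
* :class:`LabelVector` — per-cell deterministic subclass assignment.

On disk everything is plain delimited text (comma or tab, auto-detected),
except sparse counts which may also be MatrixMarket triplets with gene/cell
sidecar lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

UNASSIGNED = "UNASSIGNED"

#: Per-cell segmentation statistics required alongside a count matrix.
STAT_COLUMNS = ("n_transcripts", "elongation", "area", "avg_confidence")


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table, sniffing the delimiter."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Spot tables
# ---------------------------------------------------------------------------


@dataclass
class SpotTable:
    """Detected mRNA molecules: one record per spot with µm coordinates."""

    data: pd.DataFrame  # columns gene, x, y[, z]
    panel: list[str]

    def __post_init__(self) -> None:
        for col in ("gene", "x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"spot table missing column {col!r}")
        coords = self.data[[c for c in ("x", "y", "z") if c in self.data.columns]]
        if not np.isfinite(coords.to_numpy(dtype=float)).all():
            raise ValueError("spot coordinates must be finite")
        unknown = set(self.data["gene"]) - set(self.panel)
        if unknown:
            raise ValueError(f"genes not in panel: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Series:
        return self.data["gene"]

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)


def read_spot_table(
    path: str | Path,
    panel: Sequence[str],
    on_unknown_gene: str = "error",
) -> SpotTable:
    """Read a delimited spot table and validate its genes against ``panel``.

    Parameters
    ----------
    path
        Delimited text file with columns ``gene,x,y`` and optionally ``z``.
    panel
        Declared gene panel; records with genes outside it are rejected
        (``on_unknown_gene='error'``) or dropped with a warning
        (``on_unknown_gene='drop'``).
    """
    df = _read_delimited(path)
    for col in ("gene", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"spot table {path}: missing column {col!r}")
    for col in ("x", "y") + (("z",) if "z" in df.columns else ()):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"spot table {path}: non-numeric {col!r} at row {row}"
            ) from None
    panel = list(panel)
    unknown_mask = ~df["gene"].isin(panel)
    if unknown_mask.any():
        if on_unknown_gene == "drop":
            n = int(unknown_mask.sum())
            warnings.warn(f"dropped {n} spots with genes outside the panel")
            df = df.loc[~unknown_mask].reset_index(drop=True)
        else:
            bad = sorted(set(df.loc[unknown_mask, "gene"]))
            raise ValueError(f"genes not in panel: {bad}")
    return SpotTable(data=df.reset_index(drop=True), panel=panel)


def write_spot_table(spots: SpotTable, path: str | Path) -> None:
    spots.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------


@dataclass
class CellTable:
    """Segmented cells: raw counts plus segmentation statistics.

    ``counts`` is a cell × gene DataFrame; ``stats`` is indexed by the same
    cell ids and carries ``n_transcripts``, ``elongation``, ``area`` (µm²),
    ``avg_confidence`` and, when available, centroid ``x``/``y`` and
    cortical ``depth`` (µm from pia).
    """

    counts: pd.DataFrame
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell ids: {dups}")
        missing = self.counts.index.difference(self.stats.index)
        if len(missing):
            raise ValueError(f"cells missing stats: {missing.tolist()}")
        self.stats = self.stats.loc[self.counts.index]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def cells(self) -> list:
        return self.counts.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.counts.columns.tolist()

    def subset(self, cell_ids: Sequence) -> "CellTable":
        idx = pd.Index(cell_ids)
        return CellTable(self.counts.loc[idx], self.stats.loc[idx])


def read_cell_table(path_counts: str | Path, path_stats: str | Path) -> CellTable:
    """Read counts (delimited or MatrixMarket) joined with a stats table.

    MatrixMarket counts expect two sidecar one-name-per-line files next to
    the ``.mtx``: ``<stem>.genes.txt`` (columns) and ``<stem>.cells.txt``
    (rows).  The stats table must be keyed by a ``cell`` column covering
    every cell in the count matrix.
    """
    path_counts = Path(path_counts)
    if path_counts.suffix == ".mtx":
        mat = mmread(path_counts).toarray()
        genes = _read_name_list(path_counts.with_suffix("").with_suffix(".genes.txt"))
        cells = _read_name_list(path_counts.with_suffix("").with_suffix(".cells.txt"))
        if mat.shape != (len(cells), len(genes)):
            raise FormatError(
                f"count matrix {mat.shape} does not match sidecars "
                f"({len(cells)} cells × {len(genes)} genes)"
            )
        counts = pd.DataFrame(mat, index=cells, columns=genes)
    else:
        counts = _read_delimited(path_counts).set_index("cell")
    stats = _read_delimited(path_stats)
    if "cell" not in stats.columns:
        raise FormatError(f"stats table {path_stats}: missing 'cell' column")
    if stats["cell"].duplicated().any():
        raise ValueError("duplicate cell ids in stats table")
    stats = stats.set_index("cell")
    counts.index = counts.index.astype(stats.index.dtype, copy=False)
    missing = counts.index.difference(stats.index)
    if len(missing):
        raise ValueError(f"cells missing stats: {missing.tolist()}")
    return CellTable(counts=counts, stats=stats.loc[counts.index])


def _read_name_list(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_cell_table(
    table: CellTable, path_counts: str | Path, path_stats: str | Path
) -> None:
    """Write counts and stats as delimited text (or MatrixMarket for .mtx)."""
    path_counts = Path(path_counts)
    if path_counts.suffix == ".mtx":
        sparse = coo_matrix(table.counts.to_numpy())
        mmwrite(str(path_counts), sparse)
        stem = path_counts.with_suffix("")
        stem.with_suffix(".genes.txt").write_text(
            "\n".join(map(str, table.genes)) + "\n"
        )
        stem.with_suffix(".cells.txt").write_text(
            "\n".join(map(str, table.cells)) + "\n"
        )
    else:
        table.counts.rename_axis("cell").to_csv(path_counts)
    table.stats.rename_axis("cell").to_csv(path_stats)


# ---------------------------------------------------------------------------
# Reference profiles, confidence matrices, label vectors
# ---------------------------------------------------------------------------


@dataclass
class ReferenceProfiles:
    """Ordered subclass taxonomy with per-type expression profiles."""

    types: list[str]
    profiles: pd.DataFrame  # type × gene

    def __post_init__(self) -> None:
        if len(set(self.types)) != len(self.types):
            raise ValueError("type labels must be unique")
        if list(self.profiles.index) != list(self.types):
            raise ValueError("profile rows must match the type order")
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("expression profiles must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return self.profiles.columns.tolist()


def read_reference_profiles(path: str | Path) -> ReferenceProfiles:
    df = _read_delimited(path).set_index("type")
    return ReferenceProfiles(types=df.index.tolist(), profiles=df)


def write_reference_profiles(ref: ReferenceProfiles, path: str | Path) -> None:
    ref.profiles.rename_axis("type").to_csv(path)


@dataclass
class ConfidenceMatrix:
    """Cell × type matching scores from one method.

    Scores from individual matchers live in [0, 1] (``bounded=True``, the
    default, enforced on construction).  Combined scores from the
    negative-weighting ensemble are raw sums in [-m, m] and set
    ``bounded=False``; only their ranks are meaningful.
    """

    cells: list
    types: list[str]
    scores: np.ndarray
    method_name: str = ""
    bounded: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cells), len(self.types)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.cells)} cells × {len(self.types)} types"
            )
        bad = ~np.isfinite(self.scores)
        if self.bounded:
            bad |= (self.scores < 0) | (self.scores > 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"score out of range for cell {self.cells[i]!r}, "
                f"type {self.types[j]!r}: {self.scores[i, j]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cells, columns=self.types)


def read_confidence_matrix(
    path: str | Path, method_name: str = "", bounded: bool = True
) -> ConfidenceMatrix:
    df = _read_delimited(path).set_index("cell")
    return ConfidenceMatrix(
        cells=df.index.tolist(),
        types=df.columns.tolist(),
        scores=df.to_numpy(dtype=float),
        method_name=method_name or Path(path).stem,
        bounded=bounded,
    )


def write_confidence_matrix(
    cm: ConfidenceMatrix, path: str | Path, decimals: int = 9
) -> None:
    cm.to_frame().rename_axis("cell").round(decimals).to_csv(path)


@dataclass
class LabelVector:
    """Per-cell deterministic subclass label (or ``UNASSIGNED``)."""

    cells: list
    labels: np.ndarray
    method_name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.cells):
            raise ValueError("labels length must match cell list")

    def __len__(self) -> int:
        return len(self.cells)

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cells, name="label")


def read_label_vector(path: str | Path, method_name: str = "") -> LabelVector:
    df = _read_delimited(path)
    return LabelVector(
        cells=df["cell"].tolist(),
        labels=df["label"].to_numpy(dtype=object),
        method_name=method_name or Path(path).stem,
    )


def write_label_vector(lv: LabelVector, path: str | Path) -> None:
    lv.to_series().rename_axis("cell").to_csv(path)


# ---------------------------------------------------------------------------
# Count normalization
# ---------------------------------------------------------------------------


def normalize_counts(
    vectors: np.ndarray,
    target_libsize: float = 10.0,
    log_transform: bool = False,
) -> np.ndarray:
    """Library-size normalize expression vectors, optionally log-transform.

    Each nonzero row (or the single vector, for 1-D input) is scaled so its
    entries sum to ``target_libsize``; all-zero rows pass through as zeros so
    empty cells and background pixels flow through the pipeline.  The log
    transform is the natural ``log(1 + v)`` applied elementwise after
    scaling, which keeps zeros at zero.
    """
    if target_libsize <= 0:
        raise ValueError("target_libsize must be positive")
    arr = np.asarray(vectors, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative entries cannot be library-size normalized")
    one_dim = arr.ndim == 1
    mat = np.atleast_2d(arr)
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, mat * (target_libsize / np.where(sums > 0, sums, 1.0)), 0.0)
    if log_transform:
        out = np.log1p(out)
    return out[0] if one_dim else out


# ---------------------------------------------------------------------------
# Gene-panel accounting
# ---------------------------------------------------------------------------


@dataclass
class PanelOverlap:
    """Set accounting over named gene panels."""

    panels: dict[str, set[str]]
    pairwise: pd.DataFrame = field(init=False)
    intersection: set[str] = field(init=False)
    union: set[str] = field(init=False)

    def __post_init__(self) -> None:
        names = list(self.panels)
        counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
        for a in names:
            counts.loc[a, a] = len(self.panels[a])
        for a, b in combinations(names, 2):
            shared = len(self.panels[a] & self.panels[b])
            counts.loc[a, b] = counts.loc[b, a] = shared
        self.pairwise = counts
        sets = list(self.panels.values())
        self.intersection = set.intersection(*sets) if sets else set()
        self.union = set.union(*sets) if sets else set()


def panel_overlap(
    panels: Mapping[str, Iterable[str]], case_fold: bool = False
) -> PanelOverlap:
    """Pairwise shared-gene counts plus the global intersection and union.

    Gene-name matching is exact after an optional single case-fold step
    (``case_fold=True`` lowercases every name); no alias resolution is
    attempted.  Empty panels are kept (with a warning) as empty sets.
    """
    if not panels:
        raise ValueError("at least one panel is required")
    normalized: dict[str, set[str]] = {}
    for name, genes in panels.items():
        geneset = {g.lower() for g in genes} if case_fold else set(genes)
        if not geneset:
            warnings.warn(f"panel {name!r} is empty")
        normalized[name] = geneset
    return PanelOverlap(panels=normalized)


def read_gene_panel(path: str | Path) -> list[str]:
    """Read a one-gene-per-line panel file."""
    return _read_name_list(Path(path))


def write_gene_panel(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# Flat key-value config
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file; ``#`` starts a comment."""
    config: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line without '=': {raw!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config
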