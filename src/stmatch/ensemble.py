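"""Consensus combining of per-method confidence matrices.

Given m methods, each scoring the same c cells against the same n subclass
taxonomy, two ensemble strategies produce a single combined matrix:

* **Geometric-median combining** (:func:`gmcs_combine`): for every cell the
  m probability rows are vertices in R^n and the combined row is their
  geometric median — the point minimizing the sum of Euclidean distances to
  the vertices.  It treats every method equally and is robust to a minority
  of outlier methods (any point shared by more than half the methods is
  returned exactly).

* **Negative-weighting combining** (:func:`nwcs_combine`): per method and
  cell, keep only the top-scoring type at its score and weight every other
  type −1, then sum over methods.  Only ranks of the result matter, since
  raw confidence scores are not comparable across methods; the combined
  scores are kept raw in [−m, m].

Deterministic labels come from :func:`deterministic_assignment`: per-cell
argmax with taxonomy-order tie-breaking; all-zero rows are unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import UNASSIGNED, ConfidenceMatrix, LabelVector


@dataclass(frozen=True)
class MedianSolverConfig:
    """Stopping rule for the Weiszfeld iteration.

    ``tolerance`` is an L2 bound on the step size; iteration also stops
    after ``max_iterations`` steps.  Iterates landing exactly on a data
    point use the Vardi–Zhang corrected update instead of dividing by zero.
    """

    tolerance: float = 1e-9
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")


def weiszfeld_median(
    points: np.ndarray, cfg: MedianSolverConfig = MedianSolverConfig()
) -> np.ndarray:
    """Geometric median of m points in R^n by damped Weiszfeld iteration.

    Initialization is the componentwise mean.  For two points the mean is
    the segment midpoint, which is already optimal (the whole segment is);
    the midpoint is the deterministic, symmetric convention returned.  When
    an iterate coincides with one of the input points the Vardi–Zhang
    correction pulls it off (or certifies it as the median), avoiding the
    division by zero in the plain update.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an m × n array")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    m = pts.shape[0]
    if m == 1:
        return pts[0].copy()
    y = pts.mean(axis=0)
    for _ in range(cfg.max_iterations):
        diff = pts - y
        dist = np.linalg.norm(diff, axis=1)
        at_point = dist < 1e-14
        if at_point.any():
            # Vardi–Zhang: y sits on a data point with multiplicity eta.
            eta = float(at_point.sum())
            far = ~at_point
            if not far.any():
                return y  # all points identical
            inv = 1.0 / dist[far]
            t_tilde = (pts[far] * inv[:, None]).sum(axis=0) / inv.sum()
            r_vec = (diff[far] * inv[:, None]).sum(axis=0)
            r = np.linalg.norm(r_vec)
            if r <= eta:
                return y  # optimality condition at a vertex
            step = max(0.0, 1.0 - eta / r) * t_tilde + min(1.0, eta / r) * y
        else:
            inv = 1.0 / dist
            step = (pts * inv[:, None]).sum(axis=0) / inv.sum()
        if np.linalg.norm(step - y) < cfg.tolerance:
            return step
        y = step
    return y


def _stack_ensemble(
    matrices: list[ConfidenceMatrix], row_renormalize: bool
) -> np.ndarray:
    """Validate shared orderings and stack to an m × c × n array."""
    if not matrices:
        raise ValueError("ensemble needs at least one confidence matrix")
    first = matrices[0]
    for cm in matrices[1:]:
        if cm.cells != first.cells or cm.types != first.types:
            raise ValueError(
                f"matrix {cm.method_name!r} does not share the cell/type "
                f"ordering of {first.method_name!r}"
            )
    stack = np.stack([cm.scores for cm in matrices])
    if row_renormalize:
        sums = stack.sum(axis=2, keepdims=True)
        stack = np.where(sums > 0, stack / np.where(sums > 0, sums, 1.0), 0.0)
    return stack


def gmcs_combine(
    matrices: list[ConfidenceMatrix],
    cfg: MedianSolverConfig = MedianSolverConfig(),
    row_renormalize: bool = True,
) -> ConfidenceMatrix:
    """Per-cell geometric median of the m methods' score rows.

    ``row_renormalize`` (default on) rescales every nonzero row to sum 1
    first, since upstream methods emit scores on incomparable scales but
    the median is taken between probability rows.
    """
    stack = _stack_ensemble(matrices, row_renormalize)
    m, c, n = stack.shape
    combined = np.empty((c, n))
    for j in range(c):
        combined[j] = weiszfeld_median(stack[:, j, :], cfg)
    combined = np.clip(combined, 0.0, 1.0)  # guard fp dust at simplex edges
    return ConfidenceMatrix(
        cells=list(matrices[0].cells),
        types=list(matrices[0].types),
        scores=combined,
        method_name="GMCS",
    )


def nwcs_combine(
    matrices: list[ConfidenceMatrix],
    tie_policy: str = "all",
) -> ConfidenceMatrix:
    """Negative-weighting combination of the m methods' scores.

    Per method and cell the top-scoring type keeps its confidence score and
    every other type is set to −1; the combined matrix is the elementwise
    sum over methods.  ``tie_policy='all'`` retains every type tied for a
    method's top score; ``'first'`` keeps only the first in taxonomy order.
    """
    if tie_policy not in ("all", "first"):
        raise ValueError("tie_policy must be 'all' or 'first'")
    stack = _stack_ensemble(matrices, row_renormalize=False)
    m, c, n = stack.shape
    weighted = np.full_like(stack, -1.0)
    for k in range(m):
        top = stack[k].max(axis=1, keepdims=True)
        if tie_policy == "all":
            is_top = stack[k] == top
        else:
            is_top = np.zeros((c, n), dtype=bool)
            is_top[np.arange(c), stack[k].argmax(axis=1)] = True
        weighted[k][is_top] = stack[k][is_top]
    return ConfidenceMatrix(
        cells=list(matrices[0].cells),
        types=list(matrices[0].types),
        scores=weighted.sum(axis=0),
        method_name="NWCS",
        bounded=False,
    )


def deterministic_assignment(cm: ConfidenceMatrix) -> LabelVector:
    """Label each cell with its highest-scoring type.

    Ties go to the first tied type in taxonomy order.  Rows that are
    entirely zero (the unassignable convention of the matchers) map to
    ``UNASSIGNED``.
    """
    if len(cm.cells) == 0:
        raise ValueError("empty confidence matrix")
    best = cm.scores.argmax(axis=1)
    labels = np.asarray(cm.types, dtype=object)[best]
    zero_rows = (cm.scores == 0).all(axis=1)
    labels[zero_rows] = UNASSIGNED
    return LabelVector(
        cells=list(cm.cells), labels=labels, method_name=cm.method_name
    )
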