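"""Concordance between matchings: Cohen's kappa and overlap decompositions.

With no gold standard available for spatial cell typing, pairwise
chance-corrected agreement between methods is the practical consistency
metric.  Kappa is the unweighted multi-class form

    kappa = (p_o - p_e) / (1 - p_e)

with observed agreement ``p_o`` and the chance agreement ``p_e`` expected
from the two methods' marginal label frequencies.  Cells unassigned by
either method are excluded pairwise (and counted), since "unassigned" is a
refusal rather than a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import UNASSIGNED, LabelVector

#: Qualitative interpretation bands for kappa (upper bound inclusive).
KAPPA_BANDS = (
    (0.0, "none"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value."""
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    n_compared: int
    n_excluded: int

    @property
    def band(self) -> str:
        return kappa_band(self.kappa)


def cohens_kappa(a: LabelVector, b: LabelVector) -> KappaResult:
    """Unweighted multi-class Cohen's kappa between two labelings.

    Both vectors must cover the same cells in the same order; cells
    labeled ``UNASSIGNED`` in either are excluded and reported in
    ``n_excluded``.
    """
    if a.cells != b.cells:
        raise ValueError("label vectors must cover the same cells in order")
    la, lb = a.labels, b.labels
    keep = (la != UNASSIGNED) & (lb != UNASSIGNED)
    n_excluded = int((~keep).sum())
    la, lb = la[keep], lb[keep]
    n = len(la)
    if n == 0:
        raise ValueError("no comparable cells after excluding unassigned")
    table = pd.crosstab(pd.Series(la), pd.Series(lb))
    classes = table.index.union(table.columns)
    table = table.reindex(index=classes, columns=classes, fill_value=0)
    obs = np.diag(table.to_numpy()).sum() / n
    exp = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if exp == 1.0:
        kappa = 1.0 if obs == 1.0 else 0.0
    else:
        kappa = (obs - exp) / (1.0 - exp)
    return KappaResult(
        kappa=float(kappa), p_observed=float(obs), p_expected=exp,
        n_compared=n, n_excluded=n_excluded,
    )


def pairwise_kappa_table(
    labelings: dict[str, LabelVector]
) -> tuple[pd.DataFrame, tuple[str, str, float, str]]:
    """All-pairs kappa matrix plus the best-agreeing pair.

    Returns the symmetric kappa matrix (diagonal 1) and a tuple
    ``(method_a, method_b, kappa, band)`` for the best off-diagonal pair.
    """
    names = list(labelings)
    if len(names) < 2:
        raise ValueError("need at least two labelings")
    mat = pd.DataFrame(1.0, index=names, columns=names)
    best: tuple[str, str, float] | None = None
    for a, b in combinations(names, 2):
        k = cohens_kappa(labelings[a], labelings[b]).kappa
        mat.loc[a, b] = mat.loc[b, a] = k
        if best is None or k > best[2]:
            best = (a, b, k)
    assert best is not None
    return mat, (*best, kappa_band(best[2]))


@dataclass(frozen=True)
class OverlapReport:
    """UpSet-style decomposition of per-method matched-cell sets."""

    subclass: str
    set_sizes: dict[str, int]
    #: exact-combination bucket sizes keyed by the sorted method tuple
    buckets: dict[tuple[str, ...], int]

    @property
    def common_all(self) -> int:
        """Cells matched by every method."""
        return self.buckets.get(tuple(sorted(self.set_sizes)), 0)

    def exclusive(self, method: str) -> int:
        return self.buckets.get((method,), 0)


def subclass_overlap(
    labelings: dict[str, LabelVector], subclass: str
) -> OverlapReport:
    """Decompose which exact method combinations matched ``subclass``.

    For every nonempty combination of methods, the bucket holds the number
    of cells assigned the subclass by exactly those methods and no others —
    the quantities displayed in an UpSet plot.
    """
    if len(labelings) < 2:
        raise ValueError("need at least two labelings")
    names = list(labelings)
    known = set().union(*(set(lv.labels) for lv in labelings.values()))
    known.discard(UNASSIGNED)
    if subclass not in known:
        raise ValueError(f"unknown subclass {subclass!r}")
    sets = {
        name: {c for c, l in zip(lv.cells, lv.labels) if l == subclass}
        for name, lv in labelings.items()
    }
    buckets: dict[tuple[str, ...], int] = {}
    for cell in set().union(*sets.values()):
        combo = tuple(sorted(n for n in names if cell in sets[n]))
        buckets[combo] = buckets.get(combo, 0) + 1
    return OverlapReport(
        subclass=subclass,
        set_sizes={n: len(s) for n, s in sets.items()},
        buckets=buckets,
    )
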