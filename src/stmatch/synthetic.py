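"""Synthetic laminar-cortex data: spots, cells, references and confidences.

Everything downstream of raw imaging is exercisable from this module: it
emulates a cortical column in which depth-restricted layers host distinct
subclass mixtures, each subclass elevates a few marker genes over a shared
baseline, and each simulated imaging protocol sees only its own gene panel
at its own detection efficiency.  Counts are negative-binomial (Poisson in
the zero-dispersion limit), positions are uniform within layers, and spots
scatter isotropically around their cell centroid.

The generator also simulates an ensemble of imperfect matching methods
(:func:`generate_confidences`): each method mislabels a cell with a given
flip probability and emits a softmax-peaked confidence row, which is what
the consensus combiners consume in tests.

All outputs are bit-reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import UNASSIGNED, CellTable, ConfidenceMatrix, LabelVector, SpotTable


@dataclass(frozen=True)
class ProtocolSpec:
    """A simulated imaging protocol: its gene panel and detection rate."""

    panel: tuple[str, ...]
    efficiency: float  # per-molecule detection probability


@dataclass
class LayerSpec:
    """Laminar tissue blueprint: layers, subclass mixtures, expression."""

    layers: list[tuple[str, float, float, dict[str, float]]]
    markers: dict[str, tuple[str, ...]]  # subclass -> marker genes
    genes: list[str]  # full gene universe
    protocols: dict[str, ProtocolSpec]
    baseline_mean: float = 0.3
    marker_fold: float = 20.0
    dispersion: float = 0.5  # NB: var = mu + dispersion * mu^2; 0 -> Poisson
    width: float = 500.0  # µm extent along the pia
    spot_scatter: float = 5.0  # µm, isotropic spread of spots around centroid

    def __post_init__(self) -> None:
        prev_hi = None
        for name, lo, hi, comp in self.layers:
            if not lo < hi:
                raise ValueError(f"layer {name!r} has empty depth range")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("layer depth ranges must be contiguous")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"layer {name!r} composition does not sum to 1")
            prev_hi = hi

    @property
    def subclasses(self) -> list[str]:
        return list(self.markers)

    def mean_expression(self, subclass: str) -> np.ndarray:
        """Per-gene NB mean for a subclass (baseline + marker elevation)."""
        mu = np.full(len(self.genes), self.baseline_mean)
        marker_set = set(self.markers[subclass])
        for k, g in enumerate(self.genes):
            if g in marker_set:
                mu[k] = self.baseline_mean * self.marker_fold
        return mu


_MARKERS: dict[str, tuple[str, ...]] = {
    "Lamp5": ("Lamp5", "Cxcl14"),
    "Vip": ("Vip", "Crh"),
    "Sst": ("Sst", "Chodl"),
    "Pvalb": ("Pvalb", "Tac1"),
    "L2/3 IT": ("Cux2", "Ccbe1"),
    "L4": ("Rorb", "Rspo1"),
    "L5 IT": ("Parm1", "Etv1"),
    "L5 PT": ("Fezf2", "Bcl6"),
    "L6 IT": ("Sema3e", "Osr1"),
    "L6 CT": ("Foxp2", "Syt6"),
    "L6b": ("Ctgf", "Cplx3"),
    "Astro": ("Aqp4", "Gja1"),
}

_LAYERS: list[tuple[str, float, float, dict[str, float]]] = [
    ("L1", 0.0, 100.0, {"Lamp5": 0.5, "Vip": 0.2, "Astro": 0.3}),
    ("L2/3", 100.0, 320.0,
     {"L2/3 IT": 0.6, "Vip": 0.1, "Lamp5": 0.1, "Sst": 0.05, "Pvalb": 0.05,
      "Astro": 0.1}),
    ("L4", 320.0, 450.0,
     {"L4": 0.6, "Pvalb": 0.1, "Sst": 0.1, "Vip": 0.05, "Astro": 0.15}),
    ("L5", 450.0, 670.0,
     {"L5 IT": 0.35, "L5 PT": 0.25, "Sst": 0.1, "Pvalb": 0.1, "Astro": 0.2}),
    ("L6", 670.0, 900.0,
     {"L6 IT": 0.3, "L6 CT": 0.4, "Sst": 0.05, "Pvalb": 0.05, "Astro": 0.2}),
    ("L6b", 900.0, 1000.0, {"L6b": 0.5, "L6 CT": 0.2, "Astro": 0.3}),
]


def default_spec() -> LayerSpec:
    """Six cortical layers over 0–1000 µm, 12 subclasses, 250-gene universe.

    Four protocol presets mirror the spread of real imaging panels: a large
    combinatorially barcoded panel (``merfish``, 250 genes, efficiency
    0.7), a small sequential-FISH panel (``smfish``, 30 genes, 0.9), and
    two in situ sequencing panels (``baristaseq``, 79 genes, 0.5 and
    ``exseq``, 42 genes, 0.8).  Every panel contains all subclass markers
    so each protocol's data is matchable.
    """
    markers = [g for genes in _MARKERS.values() for g in genes]
    fillers = [f"Gene{i:03d}" for i in range(1, 250 - len(markers) + 1)]
    universe = markers + fillers

    def panel(n: int) -> tuple[str, ...]:
        return tuple(markers + fillers[: n - len(markers)])

    protocols = {
        "merfish": ProtocolSpec(panel(250), 0.7),
        "smfish": ProtocolSpec(panel(30), 0.9),
        "baristaseq": ProtocolSpec(panel(79), 0.5),
        "exseq": ProtocolSpec(panel(42), 0.8),
    }
    return LayerSpec(
        layers=list(_LAYERS), markers=dict(_MARKERS), genes=universe,
        protocols=protocols,
    )


def two_layer_spec(gene_count: int = 12, depth_split: float = 40.0) -> LayerSpec:
    """Minimal two-layer, two-subclass tissue for pixel-typing tests.

    A small, dense domain (80 µm deep) with one subclass per layer and
    strong markers, sized so kernel-density rasterization stays cheap.
    """
    markers = {"UpperType": ("MarkU1", "MarkU2"), "DeepType": ("MarkD1", "MarkD2")}
    marker_genes = [g for genes in markers.values() for g in genes]
    fillers = [f"Gene{i:03d}" for i in range(1, gene_count - len(marker_genes) + 1)]
    universe = marker_genes + fillers
    protocols = {"merfish": ProtocolSpec(tuple(universe), 0.9)}
    return LayerSpec(
        layers=[
            ("Upper", 0.0, depth_split, {"UpperType": 1.0}),
            ("Deep", depth_split, 2 * depth_split, {"DeepType": 1.0}),
        ],
        markers=markers,
        genes=universe,
        protocols=protocols,
        baseline_mean=0.5,
        marker_fold=20.0,
        width=60.0,
        spot_scatter=3.0,
    )


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, size: tuple
) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion·mu²; 0 → Poisson."""
    if dispersion <= 0:
        return rng.poisson(np.broadcast_to(mu, size))
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, np.broadcast_to(p, size))


def generate_reference(
    spec: LayerSpec, cells_per_type: int = 50, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulated dissociated-cell reference: counts plus subclass labels."""
    if cells_per_type < 1:
        raise ValueError("cells_per_type must be at least 1")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for subclass in spec.subclasses:
        mu = spec.mean_expression(subclass)
        blocks.append(
            _nb_counts(rng, mu, spec.dispersion, (cells_per_type, len(spec.genes)))
        )
        labels.extend([subclass] * cells_per_type)
    counts = pd.DataFrame(
        np.vstack(blocks),
        index=[f"ref_{i}" for i in range(len(labels))],
        columns=spec.genes,
    )
    return counts, pd.Series(labels, index=counts.index, name="subclass")


def generate_spatial(
    spec: LayerSpec,
    n_cells: int = 2000,
    protocol: str = "merfish",
    seed: int = 0,
) -> tuple[SpotTable, CellTable, LabelVector]:
    """Simulate one tissue section under a protocol preset.

    Cells are allocated to layers in proportion to layer thickness, placed
    uniformly within their layer, and typed from the layer's subclass
    mixture.  Raw per-cell counts are thinned binomially by the protocol's
    detection efficiency and restricted to its panel; each detected
    molecule becomes a spot scattered isotropically around the centroid.
    Segmentation statistics are drawn so that protocol QC presets remove a
    realistic minority of cells.

    Returns the spot table, the cell table (with depth = y) and the
    ground-truth label vector.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if protocol not in spec.protocols:
        raise ValueError(f"unknown protocol {protocol!r}")
    proto = spec.protocols[protocol]
    rng = np.random.default_rng(seed)

    thickness = np.array([hi - lo for _, lo, hi, _ in spec.layers])
    layer_idx = rng.choice(len(spec.layers), size=n_cells, p=thickness / thickness.sum())
    panel = list(proto.panel)
    panel_cols = [spec.genes.index(g) for g in panel]

    xs = rng.uniform(0.0, spec.width, n_cells)
    depths = np.empty(n_cells)
    labels = np.empty(n_cells, dtype=object)
    counts = np.empty((n_cells, len(panel)), dtype=np.int64)
    for i in range(n_cells):
        name, lo, hi, comp = spec.layers[layer_idx[i]]
        depths[i] = rng.uniform(lo, hi)
        subclass = rng.choice(list(comp), p=list(comp.values()))
        labels[i] = subclass
        mu = spec.mean_expression(subclass)[panel_cols]
        raw = _nb_counts(rng, mu, spec.dispersion, (len(panel),))
        counts[i] = rng.binomial(raw, proto.efficiency)

    cell_ids = [f"cell_{i}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=cell_ids, columns=panel)

    n_tx = counts.sum(axis=1)
    stats = pd.DataFrame(
        {
            "n_transcripts": n_tx,
            "elongation": rng.lognormal(np.log(2.5), 0.5, n_cells),
            "area": rng.lognormal(np.log(8000.0), 0.6, n_cells),
            "avg_confidence": rng.beta(20.0, 2.0, n_cells),
            "x": xs,
            "y": depths,
            "depth": depths,
        },
        index=cell_ids,
    )
    cells = CellTable(counts=counts_df, stats=stats)

    per_gene = counts.ravel()
    total_spots = int(per_gene.sum())
    gene_rep = np.tile(np.arange(len(panel)), n_cells)
    cell_rep = np.repeat(np.arange(n_cells), len(panel))
    spot_gene = np.repeat(gene_rep, per_gene)
    spot_cell = np.repeat(cell_rep, per_gene)
    spot_xy = np.column_stack([xs[spot_cell], depths[spot_cell]])
    spot_xy += rng.normal(0.0, spec.spot_scatter, (total_spots, 2))
    spots = SpotTable(
        data=pd.DataFrame(
            {
                "gene": np.asarray(panel, dtype=object)[spot_gene],
                "x": spot_xy[:, 0],
                "y": spot_xy[:, 1],
            }
        ),
        panel=panel,
    )
    truth = LabelVector(cells=cell_ids, labels=labels, method_name="truth")
    return spots, cells, truth


@dataclass(frozen=True)
class NoiseModel:
    """Error model for a simulated ensemble of matching methods.

    Each method mislabels a cell with probability ``flip_probability``
    (to a uniformly drawn wrong type) and reports a softmax confidence row
    peaked at its chosen type; smaller ``temperature`` means sharper rows.
    """

    flip_probability: float = 0.25
    temperature: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability < 1.0:
            raise ValueError("flip probability must lie in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def generate_confidences(
    truth: LabelVector,
    types: list[str],
    m: int = 5,
    noise: NoiseModel = NoiseModel(),
) -> list[ConfidenceMatrix]:
    """Simulate m methods' confidence matrices around a ground truth.

    Per method and cell: flip to a wrong type with the model's flip
    probability, then emit ``softmax(logits / temperature)`` where the
    chosen type has logit 1 and the others draw uniformly from [0, 0.5) —
    so the chosen type always holds the row maximum and the temperature→0
    limit is exactly one-hot.
    """
    if m < 1:
        raise ValueError("need at least one simulated method")
    rng = np.random.default_rng(noise.seed)
    type_index = {t: k for k, t in enumerate(types)}
    truth_idx = np.array([type_index[l] for l in truth.labels])
    c, n = len(truth), len(types)
    out = []
    for method in range(m):
        chosen = truth_idx.copy()
        flip = rng.random(c) < noise.flip_probability
        # uniform wrong type: shift by 1..n-1 modulo n
        offsets = rng.integers(1, n, size=c)
        chosen[flip] = (chosen[flip] + offsets[flip]) % n
        logits = rng.uniform(0.0, 0.5, (c, n))
        logits[np.arange(c), chosen] = 1.0
        z = logits / noise.temperature
        z -= z.max(axis=1, keepdims=True)
        expz = np.exp(z)
        scores = expz / expz.sum(axis=1, keepdims=True)
        out.append(
            ConfidenceMatrix(
                cells=list(truth.cells), types=list(types), scores=scores,
                method_name=f"sim_{method}",
            )
        )
    return out


def accuracy(labels: LabelVector, truth: LabelVector) -> float:
    """Fraction of assigned cells whose label matches the ground truth."""
    if labels.cells != truth.cells:
        raise ValueError("label vectors must cover the same cells in order")
    assigned = labels.labels != UNASSIGNED
    if not assigned.any():
        return float("nan")
    return float((labels.labels[assigned] == truth.labels[assigned]).mean())


def synthetic_protocol_panels() -> dict[str, set[str]]:
    """Synthetic stand-in for the four imaging protocols' gene panels.

    The real panel memberships are not reproduced here; this construction
    matches their published set arithmetic exactly — per-protocol sizes
    253 (merfish), 22 (smfish), 79 (baristaseq) and 42 (exseq), six genes
    shared by all four, and a union of 314 genes — so panel accounting is
    testable without the original tables.
    """
    core = ["Cux2", "Rorb", "Fezf2", "Foxp2", "Sst", "Pvalb"]

    def filler(prefix: str, n: int) -> list[str]:
        return [f"{prefix}{i:03d}" for i in range(1, n + 1)]

    sm_shared = filler("SM", 16)  # smFISH extras, also probed by MERFISH
    ex_shared = filler("EXM", 30)  # ExSeq genes shared with MERFISH
    ex_only = filler("EXO", 6)
    ba_shared = filler("BAM", 18)  # BaristaSeq genes shared with MERFISH
    ba_only = filler("BAO", 55)
    mer_only = filler("MER", 183)

    panels = {
        "merfish": set(core + sm_shared + ex_shared + ba_shared + mer_only),
        "smfish": set(core + sm_shared),
        "baristaseq": set(core + ba_shared + ba_only),
        "exseq": set(core + ex_shared + ex_only),
    }
    return panels
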