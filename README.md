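# stmatch

Consensus cell-type matching for imaging-based spatial transcriptomics.

Multiplexed FISH and in situ sequencing protocols measure the locations of
individual mRNA molecules in tissue sections. After segmentation, each
cell's small gene panel must be matched to reference cell types defined by
scRNA-seq — but different matching algorithms disagree substantially, and
no gold standard exists to pick a winner. `stmatch` implements the
ensemble answer: run several matchers, combine their per-cell confidence
scores into a consensus, and validate the result against the laminar
organization of the tissue.

The package provides:

- **Correlation matchers** — per-cell Pearson correlation against
  per-subclass reference profiles, converted to probabilities with the
  scaled transform `p_i ∝ max(y_i − max(y)/2, 0)²`, plus a gene-subsampling
  bootstrap variant whose confidence is the vote fraction over rounds.
- **Ensemble combiners** — GMCS (per-cell geometric median of the m
  methods' probability rows, solved by Weiszfeld iteration with the
  Vardi–Zhang correction) and NWCS (each method keeps its top score per
  cell, weights every other type −1, and the matrices are summed; only
  ranks are used downstream).
- **Agreement statistics** — multi-class Cohen's kappa
  `κ = (p_o − p_e)/(1 − p_e)` with pairwise exclusion of unassigned cells,
  and UpSet-style overlap decompositions of matched-cell sets.
- **QC and depth profiling** — per-protocol segmentation-statistics
  filters with exact boundary semantics, polygon region cropping, and
  25 µm cortical-depth bin statistics comparing individual and combined
  matchings.
- **Guided segmentation-free typing** — per-gene Gaussian KDE vector
  fields (σ = 2.5 µm) from raw spots, correlated per pixel against
  signatures built from labeled cells, thresholded at correlation 0.6.
- **A synthetic laminar-cortex generator** — layer-restricted subclasses,
  marker panels, protocol-dependent panel subsetting and detection
  efficiency, and simulated noisy method ensembles, all with ground truth.

## Worked example

```python
import numpy as np
from stmatch import (
    LabelVector, QC_PRESETS, deterministic_assignment, filter_cells,
    gmcs_combine, nwcs_combine, match_correlation,
)
from stmatch.matcher import cluster_profiles
from stmatch.synthetic import (
    NoiseModel, accuracy, default_spec, generate_confidences,
    generate_reference, generate_spatial,
)

spec = default_spec()
spots, cells, truth = generate_spatial(spec, n_cells=2000, protocol="merfish", seed=1)

kept, removed = filter_cells(cells, QC_PRESETS["merfish"])
print(len(cells), "cells,", len(kept), "after QC")

ref = cluster_profiles(*generate_reference(spec, 50, seed=2), type_order=spec.subclasses)
labels = deterministic_assignment(match_correlation(kept, ref))
kept_truth = LabelVector(cells=kept.cells,
                         labels=truth.to_series()[kept.cells].to_numpy())
print("matcher accuracy:", accuracy(labels, kept_truth))

methods = generate_confidences(truth, spec.subclasses, m=5,
                               noise=NoiseModel(flip_probability=0.25, seed=3))
for name, combine in [("GMCS", gmcs_combine), ("NWCS", nwcs_combine)]:
    consensus = deterministic_assignment(combine(methods))
    print(name, "consensus accuracy:", accuracy(consensus, truth))
```

prints

```
2000 cells, 1416 after QC
matcher accuracy: 0.9378531073446328
GMCS consensus accuracy: 0.9705
NWCS consensus accuracy: 0.972
```

QC removed cells with segmentation statistics outside the protocol preset;
the correlation matcher recovers ~94% of planted subclass labels from the
QC-passing cells; and both consensus strategies, combining five simulated
methods that are individually ~75% accurate (flip probability 0.25), reach
~97% — the ensemble effect the package exists to exploit.

The same pipeline is scriptable from the shell via the `stmatch` CLI
(`simulate`, `qc`, `match`, `combine`, `agree`, `depth`, `ssam`
subcommands); all files are plain delimited text or MatrixMarket.

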