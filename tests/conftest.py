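import numpy as np
import pandas as pd
import pytest

from stmatch import CellTable, LabelVector
from stmatch.synthetic import default_spec, generate_reference, generate_spatial


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def tissue(spec):
    """Default synthetic section: (spots, cells, truth) at n=2000."""
    return generate_spatial(spec, n_cells=2000, protocol="merfish", seed=11)


@pytest.fixture(scope="session")
def reference(spec):
    """Simulated dissociated reference (counts, labels)."""
    return generate_reference(spec, cells_per_type=50, seed=12)


def make_cells(counts, stats=None, genes=None):
    """Small CellTable builder for unit tests."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n, g = counts.shape
    ids = [f"c{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    counts_df = pd.DataFrame(counts, index=ids, columns=genes)
    base = pd.DataFrame(
        {
            "n_transcripts": counts.sum(axis=1),
            "elongation": 2.0,
            "area": 5000.0,
            "avg_confidence": 0.9,
            "x": np.arange(n, dtype=float),
            "y": np.arange(n, dtype=float),
            "depth": np.arange(n, dtype=float),
        },
        index=ids,
    )
    if stats is not None:
        for col, vals in stats.items():
            base[col] = vals
    return CellTable(counts=counts_df, stats=base)


def labvec(labels, cells=None, name=""):
    labels = np.asarray(labels, dtype=object)
    cells = cells if cells is not None else list(range(len(labels)))
    return LabelVector(cells=list(cells), labels=labels, method_name=name)
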