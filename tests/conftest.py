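import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scpoem._types import MultiomeDataset
from scpoem.synthetic import SyntheticConfig, generate, worked_example


def make_dataset(n_cells=6, n_peaks=4, n_genes=3, seed=0, chroms=("chr1",)):
    """Small hand-buildable dataset for unit tests."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n_cells, n_peaks))
    Y = rng.integers(0, 6, size=(n_cells, n_genes))
    X[:, 0] = np.maximum(X[:, 0], 1)  # keep cells nonempty
    Y[:, 0] = np.maximum(Y[:, 0], 1)
    peaks = pd.DataFrame(
        {
            "chrom": [chroms[i % len(chroms)] for i in range(n_peaks)],
            "start": [1000 * (i + 1) for i in range(n_peaks)],
            "end": [1000 * (i + 1) + 500 for i in range(n_peaks)],
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{j}" for j in range(n_genes)],
            "symbol": [f"G{j}" for j in range(n_genes)],
            "chrom": [chroms[j % len(chroms)] for j in range(n_genes)],
            "start": [2000 * (j + 1) for j in range(n_genes)],
            "end": [2000 * (j + 1) + 800 for j in range(n_genes)],
            "strand": ["+", "-"] * (n_genes // 2) + ["+"] * (n_genes % 2),
        }
    )
    return MultiomeDataset(
        X=sp.csr_matrix(X),
        Y=sp.csr_matrix(Y),
        cell_ids=[f"bc{i}" for i in range(n_cells)],
        peaks=peaks,
        genes=genes,
    )


@pytest.fixture
def tiny_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def example():
    """The fixed worked example with hand-built networks (no dead rows)."""
    return worked_example()


@pytest.fixture(scope="session")
def synthetic_default():
    """One draw of the default study conditions, with ground truth."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def small_synthetic():
    """Smaller synthetic instance for mid-weight stage tests."""
    cfg = SyntheticConfig(n_cells=200, n_peaks=60, n_genes=12, n_modules=3,
                          n_linked_genes=8, peak_block_size=6, seed=5)
    return generate(cfg)
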