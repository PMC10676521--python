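import warnings

import numpy as np
import pytest

from citegate.containers import AdtVector, CountMatrix
from citegate.synthetic import SimConfig, simulate, worked_toy

# the cell-cycle scorer warns when the synthetic panel lacks phase genes;
# that is expected on fixtures
warnings.filterwarnings("ignore", message="only .* genes found")


@pytest.fixture(scope="session")
def sim_small():
    """Modest synthetic CITE-seq dataset shared across tests."""
    return simulate(SimConfig(n_cells=600, n_genes=300, seed=11))


@pytest.fixture(scope="session")
def toy():
    return worked_toy()


@pytest.fixture
def tiny_matrix():
    """4 cells x 5 genes with hand-set counts for QC rules."""
    genes = ["CD3E", "CD19", "RPS1", "RPL2", "G1"]
    counts = np.array(
        [
            [2, 0, 50, 50, 5],   # T cell, high ribo
            [2, 1, 50, 50, 5],   # CD19+ -> gated out
            [0, 0, 50, 50, 5],   # no CD3 -> gated out
            [2, 0, 2, 2, 96],    # T cell, ribo 4/102 < 5%
        ]
    )
    cells = [f"c{i}" for i in range(1, 5)]
    return CountMatrix(counts, genes, cells)


def make_adt(values, prefix="c"):
    values = np.asarray(values, dtype=float)
    return AdtVector(values, [f"{prefix}{i}" for i in range(1, len(values) + 1)])
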