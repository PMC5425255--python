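import numpy as np
import pandas as pd
import pytest

from nmpgrn import synthetic_data
from nmpgrn.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def branching():
    """Moderate-noise bifurcating matrix shared across read-only tests."""
    spec = synthetic_data.BranchingSpec(
        n_cells_per_branch=100, n_genes=120,
        program_sizes={"nmp": 30, "mesoderm": 30, "neural": 30,
                       "housekeeping": 30},
        nb_dispersion=0.05, dropout_rate=0.1, library_size_mean=1e5, seed=42)
    return synthetic_data.simulate_branching_counts(spec)


@pytest.fixture(scope="session")
def clean_branching():
    """Noise-free (Poisson, no dropout) matrix for structure-recovery tests."""
    spec = synthetic_data.BranchingSpec(
        n_cells_per_branch=100, n_genes=80,
        program_sizes={"nmp": 20, "mesoderm": 20, "neural": 20,
                       "housekeeping": 20},
        nb_dispersion=0.0, dropout_rate=0.0, library_size_mean=2e5, seed=7)
    return synthetic_data.simulate_branching_counts(spec)


def toy_matrix(values, layer="counts", genes=None, cells=None, **kw):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells),
                            layer=layer, **kw)
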