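import numpy as np
import pandas as pd
import pytest

from scqpcr.preprocess import cq_to_molecules, log2_matrix
from scqpcr.simulate import GroupSpec, SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def planted_dataset():
    """Strongly separable two-phase dataset: 4 informative genes among 20."""
    cfg = SimulationConfig(
        n_genes=20,
        n_informative_phase=4,
        phase_fold_changes=2.0,
        n_informative_size=0,
        groups=(GroupSpec("G1", "small", 15), GroupSpec("G1", "large", 15),
                GroupSpec("G2M", "small", 15), GroupSpec("G2M", "large", 15)),
        seed=42,
    )
    cq, ann, truth = generate_dataset(cfg)
    log2 = log2_matrix(cq_to_molecules(cq))
    return cfg, cq, ann, truth, log2


def make_expression(values, cells=None, genes=None, detected=None):
    """Small helper to build an ExpressionMatrix from a plain array."""
    from scqpcr.preprocess import ExpressionMatrix

    values = np.asarray(values, dtype=float)
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=cells, columns=genes)
    det = (
        pd.DataFrame(np.asarray(detected, dtype=bool), index=cells, columns=genes)
        if detected is not None
        else pd.DataFrame(True, index=cells, columns=genes)
    )
    return ExpressionMatrix(molecules=df, detected=det)
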