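import numpy as np
import pandas as pd
import pytest

from spiralcompare.expression import ExpressionMatrix, StageDesign
from spiralcompare.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down default-conditions dataset (600 genes/species, seed 7)."""
    return generate_dataset(SimulationConfig(n_genes_per_species=600, seed=7))


@pytest.fixture(scope="session")
def medium_dataset():
    """Mid-size dataset for recovery-style unit tests (2000 genes/species)."""
    return generate_dataset(SimulationConfig(n_genes_per_species=2000, seed=11))


def make_matrix(values, stages, n_replicates, unit="tpm", genes=None):
    """ExpressionMatrix from an array laid out stage-major (s1_r1, s1_r2, s2_r1...)."""
    design = StageDesign.default(tuple(stages), n_replicates)
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=genes, columns=list(design.samples.index))
    return ExpressionMatrix(frame, unit, design)


@pytest.fixture
def two_stage_counts():
    """4 genes x (2 stages x 2 reps) toy count matrix."""
    vals = np.array(
        [
            [10, 12, 40, 44],
            [100, 90, 95, 105],
            [5, 7, 6, 4],
            [0, 0, 30, 25],
        ]
    )
    return make_matrix(vals, ["s0", "s1"], 2, unit="counts")
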