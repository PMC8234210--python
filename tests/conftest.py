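import numpy as np
import pandas as pd
import pytest

from nfypipe.data_model import ExpressionMatrix
from nfypipe.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with all planted structure, shared across tests."""
    config = CohortConfig(n_tumor=120, n_normal=20, n_genes=800,
                          n_signature_genes_per_subtype=40, seed=11)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def tiny_expression():
    """4 genes x 6 samples linear-TPM matrix with easy-to-track values."""
    data = pd.DataFrame(
        np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            [0.0, 1.0, 0.0, 2.0, 0.0, 3.0],
            [5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
        ]),
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    return ExpressionMatrix(data)
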