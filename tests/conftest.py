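import numpy as np
import pandas as pd
import pytest

from pharmflow.dose_response import ExpressionMatrix
from pharmflow.synthetic import SimulationConfig, gen_expression


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, concentrations, cell_systems=None, feature_ids=None):
    """Build an ExpressionMatrix from a plain array and concentration list."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_feat, n_samp = values.shape
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(1, n_feat + 1)]
    if cell_systems is None:
        cell_systems = ["cs1"] * n_samp
    samples = [f"s{i}" for i in range(n_samp)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        sample_meta=pd.DataFrame(
            {
                "concentration": list(concentrations),
                "cell_system": list(cell_systems),
                "time": "6h",
                "replicate": 1,
            },
            index=samples,
        ),
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """A moderate synthetic dataset shared by several test modules."""
    cfg = SimulationConfig(
        n_genes=200,
        n_cell_systems=2,
        replicates_per_condition=2,
        n_responders=30,
        noise_sd=0.2,
        seed=11,
    )
    return gen_expression(cfg)


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = SimulationConfig(
        n_genes=120,
        n_cell_systems=2,
        replicates_per_condition=1,
        n_responders=20,
        noise_sd=0.0,
        seed=5,
    )
    return gen_expression(cfg)
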