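import numpy as np
import pandas as pd
import pytest

from cernet import SimulationConfig, simulate_expression
from cernet.matrix import ExpressionMatrix


def make_matrix(values, rna_class="mRNA", n_per_group=None, features=None):
    """ExpressionMatrix from a 2-D array with A1..An, H1..Hn columns."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1] // 2 if n_per_group is None else n_per_group
    cols = [f"A{i+1}" for i in range(n)] + [f"H{i+1}" for i in range(values.shape[1] - n)]
    feats = features or [f"f{i+1}" for i in range(values.shape[0])]
    samples = pd.DataFrame(
        {"group": ["A"] * n + ["H"] * (values.shape[1] - n),
         "pair": [f"P{i+1}" for i in range(n)] + [f"P{i+1}" for i in range(values.shape[1] - n)]},
        index=pd.Index(cols, name="sample"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(feats, name="feature"), columns=cols),
        rna_class=rna_class,
        samples=samples,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One simulation at the default study conditions, shared across tests."""
    config = SimulationConfig(seed=11)
    matrices, truth = simulate_expression(config)
    return config, matrices, truth
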