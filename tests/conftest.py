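import numpy as np
import pandas as pd
import pytest

from polygero.synth import (
    SyntheticConfig,
    generate_labeled_matrix,
    generate_smiles_library,
    make_cluster_map,
)


@pytest.fixture(scope="session")
def small_matrix_labels():
    """A noise-free fully observed planted-rule matrix with its labels."""
    cfg = SyntheticConfig(n_compounds=200, n_clusters=10, label_noise_eps=0.0,
                          observe_prob_rho=1.0, background_active_prob=0.1,
                          seed=11)
    matrix, labels = generate_labeled_matrix(cfg)
    return cfg, matrix, labels


@pytest.fixture(scope="session")
def toy_library():
    return generate_smiles_library(60, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_binary_frame(rng, n=50, g=8, p=0.3):
    cols = [f"cl{j}" for j in range(g)]
    idx = [f"CPD{i:04d}" for i in range(n)]
    return pd.DataFrame((rng.random((n, g)) < p).astype(int), index=idx, columns=cols)
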