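import numpy as np
import pandas as pd
import pytest

from doepred.simulate import SimConfig, generate_gene_universe


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but fully featured simulation configuration."""
    return SimConfig(n_genes=300, n_drugs=400, n_diseases=30,
                     embed_dim_gene=16, embed_dim_protein=8,
                     embed_dim_protein_raw=24, seed=1)


@pytest.fixture(scope="session")
def small_universe(small_cfg):
    return generate_gene_universe(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scored_sample():
    """A fixed (scores, labels) sample with both classes present."""
    r = np.random.default_rng(7)
    labels = r.integers(0, 2, size=200)
    scores = r.normal(size=200) + labels
    return scores, labels
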