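import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from drvae.models import Batch, ModelConfig, init_params
from drvae.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A model small enough for finite differences and quadrature."""
    return ModelConfig(n_genes=1, latent_dim=1, z3_dim=1,
                       enc_hidden=3, aux_hidden=3,
                       max_epochs=5, patience=3, class_weight_grid=(1.0,))


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config, seed=7)


@pytest.fixture
def small_config():
    return ModelConfig(n_genes=20, latent_dim=3, z3_dim=3,
                       enc_hidden=12, aux_hidden=8,
                       max_epochs=60, patience=15,
                       class_weight_grid=(1.0,), batch_size=64)


@pytest.fixture
def small_dataset():
    """Synthetic fixture: 8 pair cell lines x 2 pairs, 60 singletons."""
    return generate(SyntheticConfig(
        n_genes=20, latent_dim_true=3, n_cell_lines_pairs=8,
        pairs_per_cell_line=2, n_singletons=60, noise_sd_gene=0.05,
        replicate_sd=0.05, seed=11))


@pytest.fixture
def small_batch(small_dataset):
    return small_dataset.to_batch()
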