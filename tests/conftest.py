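import numpy as np
import pytest

from cellstack.io_core import CellSet
from cellstack.model import ModelConfig, StackModel


def make_cellset(counts, sample_id="s0", cell_type=None, condition=None, genes=None):
    counts = np.asarray(counts)
    k, g = counts.shape
    return CellSet(
        counts=counts,
        genes=np.array([f"g{i}" for i in range(g)], dtype=object) if genes is None else genes,
        cell_ids=np.array([f"c{i}" for i in range(k)], dtype=object),
        sample_id=sample_id,
        cell_type=cell_type,
        condition=condition,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    return ModelConfig(n_genes=30, n_layers=2, n_tokens=4, token_dim=4,
                       heads_intra=2, heads_inter=4)


@pytest.fixture
def tiny_model(tiny_config):
    return StackModel(tiny_config, rng=np.random.default_rng(11))


@pytest.fixture
def random_cells(rng):
    counts = rng.poisson(4.0, size=(12, 30))
    counts[:, 0] += 1  # avoid all-zero cells
    return make_cellset(counts)
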