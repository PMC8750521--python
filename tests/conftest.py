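import numpy as np
import pytest

from orthoae import (
    AEHyperparams,
    ExpressionMatrix,
    GeneSetCollection,
    demo_spec,
    generate_dataset,
    normalize_log_cpm,
    train_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-module counts dataset with labels (120 cells x 60
    genes, 3 types, 3 modules)."""
    spec = demo_spec(7, n_genes=60, n_modules=3, module_size=10,
                     cells_per_type=40, n_types=3)
    m, labels, modules = generate_dataset(spec)
    return m, modules


@pytest.fixture(scope="session")
def small_logcpm(small_dataset):
    m, modules = small_dataset
    return normalize_log_cpm(m), modules


@pytest.fixture(scope="session")
def small_hp():
    return AEHyperparams(lr=1e-2, hidden_size=16, bottleneck_size=6,
                         epochs=15, patience=100, seed=3)


@pytest.fixture(scope="session")
def small_model(small_logcpm, small_hp):
    ml, _ = small_logcpm
    model, history = train_model(ml, small_hp)
    return model


def tiny_matrix(n_cells=5, n_genes=4, seed=0, labels=None, space="counts"):
    rng = np.random.default_rng(seed)
    values = rng.poisson(5.0, size=(n_cells, n_genes)).astype(float) + 1.0
    return ExpressionMatrix(
        values,
        [f"g{j}" for j in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
        labels=labels,
        space=space,
    )
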