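import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fcgnet
from fcgnet.quant import collapse_replicates, relative_expression

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return fcgnet.default_config(n_per_group=5, seed=11)


@pytest.fixture(scope="session")
def dataset(small_config):
    """(design, ct_long, behavior, directions, truth) for a small study."""
    return fcgnet.generate_dataset(small_config)


@pytest.fixture(scope="session")
def expression(dataset, small_config):
    _design, ct_long, *_ = dataset
    ct_mean, _ = collapse_replicates(ct_long)
    return relative_expression(ct_mean, small_config.reference_genes)


def make_weight_network(W, genes=None):
    """Wrap a symmetric weight matrix as a CoexpressionNetwork for
    property tests (corr = cube root of weight, positive sign)."""
    W = np.asarray(W, float)
    n = W.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    corr = np.cbrt(W)
    np.fill_diagonal(corr, 0.0)
    return fcgnet.CoexpressionNetwork(
        genes=list(genes), corr=corr, weight=W.copy(), n_samples=0
    )


def random_weight_matrix(rng, n):
    """Random symmetric weight matrix with entries in (0, 1)."""
    a = rng.uniform(0.05, 1.0, size=(n, n))
    W = (a + a.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return W


@pytest.fixture
def weight_network_factory():
    return make_weight_network


@pytest.fixture
def random_weights():
    return random_weight_matrix
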