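"""Shared fixtures: synthetic datasets and the (expensive) default network.

The seed-1 default synthetic dataset and its built network are
session-scoped so recovery, enrichment and classification tests share one
network build.
"""

import numpy as np
import pandas as pd
import pytest

from gmsca.containers import ExpressionMatrix
from gmsca.enrichment import assign_cell_types
from gmsca.gcn import build_network
from gmsca.synthetic import CellTypeSpec, SyntheticConfig, simulate_bulk


@pytest.fixture(scope="session")
def default_dataset():
    """Documented default scenario: 2080 genes × 150 samples, seed 1."""
    return simulate_bulk(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_network(default_dataset):
    return build_network(default_dataset.expr)


@pytest.fixture(scope="session")
def default_annotation(default_dataset, default_network):
    return assign_cell_types(default_network, default_dataset.marker_sets())


def small_config(seed, n_types=2, n_genes=120, n_markers=30,
                 n_background=200, n_multifunctional=20, n_samples=60):
    names = ["alpha", "beta", "gamma", "delta"][:n_types]
    return SyntheticConfig(
        seed=seed,
        cell_types=[CellTypeSpec(n, n_genes, n_markers) for n in names],
        n_background_genes=n_background,
        n_multifunctional=n_multifunctional,
        n_samples=n_samples,
    )


@pytest.fixture
def small_dataset():
    return simulate_bulk(small_config(seed=2))


def random_expr(rng, n_genes=20, n_samples=30, prefix="g"):
    return ExpressionMatrix(pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
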