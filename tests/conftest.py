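"""Shared fixtures: synthetic study data, spatial graphs, trained models.

Heavy artifacts (the default simulated slide and one trained model) are
session-scoped so the whole suite pays for them once.
"""

import numpy as np
import pytest
import scipy.sparse as sp

from spagae.datasets import QcConfig, SpatialDataset
from spagae.graph import build_sng
from spagae.model import GaaeConfig, train
from spagae.preprocess import preprocess
from spagae.synthetic import SimConfig, simulate_dataset

# desk-scale training configuration used throughout the suite
DESK_MODEL = dict(layer_dims=(64, 16), epochs=300, learning_rate=1e-3,
                  lambda_struct=0.1)


@pytest.fixture(scope="session")
def sim():
    """Default synthetic study: 20x20 hex lattice, 4 domains, 200 genes."""
    return simulate_dataset(SimConfig(noise_seed=0))


@pytest.fixture(scope="session")
def processed(sim):
    ds, _ = sim
    return preprocess(ds, QcConfig())


@pytest.fixture(scope="session")
def graph(processed):
    return build_sng(processed.coords)


@pytest.fixture(scope="session")
def trained(processed, graph):
    cfg = GaaeConfig(seed=0, **DESK_MODEL)
    return train(processed, graph, cfg)


@pytest.fixture()
def small_random_graph():
    """Irregular 10-node graph with expression, for brute-force oracles."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 4, size=(10, 2))
    g = build_sng(coords, mode="knn", k=3)
    X = rng.normal(size=(10, 5))
    return g, X


def make_dataset(counts, coords=None, gene_ids=None, spot_ids=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    return SpatialDataset(
        counts=sp.csr_matrix(counts),
        coords=np.random.default_rng(0).uniform(0, 10, (n, 2))
        if coords is None else np.asarray(coords, float),
        spot_ids=spot_ids or [f"s{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(m)],
    )


@pytest.fixture()
def tiny_counts_dataset():
    rng = np.random.default_rng(7)
    return make_dataset(rng.poisson(3, size=(12, 8)) + 1)
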