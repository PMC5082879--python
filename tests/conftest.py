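"""Shared fixtures: tiny hand-built datasets and seeded simulations."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netdiscrim import diffexpr, simulate
from netdiscrim.io import ExpressionDataset


def make_dataset(values, genes, samples, labels, reference="LMP"):
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    lab = pd.Series(labels, index=samples, name="phenotype")
    return ExpressionDataset(df, lab, reference)


@pytest.fixture
def tiny_ds():
    """3 genes x 4 samples, 2 LMP + 2 HGSOC."""
    return make_dataset(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.0, 1.0, 0.0, 1.0]],
        ["GA", "GB", "GC"],
        ["s1", "s2", "s3", "s4"],
        ["LMP", "LMP", "HGSOC", "HGSOC"],
    )


@pytest.fixture(scope="session")
def sim_graph():
    return simulate.generate_ppi(500, 2, 7)


@pytest.fixture(scope="session")
def sim_default(sim_graph):
    """Default planted-signal simulation, seed 42."""
    cfg = simulate.SimulationConfig(rng_seed=42)
    ds, truth = simulate.generate_dataset(cfg, sim_graph)
    return ds, truth


@pytest.fixture(scope="session")
def sim_zds(sim_default):
    ds, _ = sim_default
    return diffexpr.zscore_normalize(ds)


@pytest.fixture
def star_graph():
    """A 4-leaf star around 'HUB' plus a distance-2 tail."""
    g = nx.Graph()
    g.add_edges_from(
        [("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3"), ("HUB", "L4"), ("L1", "T1")]
    )
    return g
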