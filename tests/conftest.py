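import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexdiff import communities as comm
from coexdiff import minet, preprocess, synthetic_data as sd


@pytest.fixture(scope="session")
def benchmark_run():
    """Full pipeline on the planted benchmark design (shared across tests).

    2,000 genes, ten modules of 50, latent rho 0.8, 150 samples per
    condition, 20% round-robin rearrangement, seed 42. The network is
    thresholded at the 99.5th percentile, which at a 2,000-gene universe
    retains an edge mass comparable to the planted within-module pairs.
    """
    design = sd.make_design(seed=42)
    mat_a, mat_b, truth = sd.generate_two_condition_counts(design)
    out = {"design": design, "truth": truth}
    for name, mat in (("A", mat_a), ("B", mat_b)):
        filtered = preprocess.cpm_filter(mat)
        normalized = preprocess.normalize(filtered, preprocess.tmm_factors(filtered))
        mi = minet.mi_matrix(minet.discretize(normalized))
        net = minet.threshold_by_percentile(mi, 99.5)
        part = comm.infomap_partition(net, n_trials=5, seed=1)
        out[name] = {"counts": mat, "normalized": normalized, "mi": mi,
                     "net": net, "partition": part}
    return out


@pytest.fixture
def toy_counts():
    """10-gene, 3-sample integer count matrix with equal library sizes."""
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 50, size=(10, 3))
    vals[0] = [0, 1, 0]          # mean CPM below 1 at library size 1e6
    vals[1] = [2, 2, 2]
    vals = pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                        columns=["s0", "s1", "s2"])
    # pad one gene so every library size is exactly 1e6
    pad = 1_000_000 - vals.sum(axis=0)
    vals.loc["gpad"] = pad.to_numpy()
    return preprocess.CountMatrix(values=vals)


@pytest.fixture
def barbell_graph():
    """Two triangles joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by one edge."""
    g = nx.Graph()
    for off in (0, 4):
        g.add_edges_from(itertools.combinations(range(off, off + 4), 2))
    g.add_edge(0, 4)
    return g


def random_connected_graph(n, p, rng):
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return g


@pytest.fixture
def normalized_from(request):
    return make_normalized


def make_normalized(values: np.ndarray) -> preprocess.NormalizedMatrix:
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=[f"s{j}" for j in range(values.shape[1])])
    return preprocess.NormalizedMatrix(
        values=df, normalization_factors=pd.Series(1.0, index=df.columns))
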