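import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexdiff import topology as topo
from tests.conftest import random_connected_graph


class TestDegreeSummary:
    def test_triangle_all_degree_two(self):
        s = topo.degree_summary(nx.complete_graph(3))
        assert s.histogram.to_dict() == {2: 1.0}

    def test_star_degrees(self):
        s = topo.degree_summary(nx.star_graph(4))
        assert s.histogram.to_dict() == {1: 0.8, 4: 0.2}

    def test_cumulative_is_one_at_min_degree(self):
        g = random_connected_graph(12, 0.4, np.random.default_rng(0))
        s = topo.degree_summary(g)
        assert s.cumulative.iloc[0] == pytest.approx(1.0)
        assert (np.diff(s.cumulative.to_numpy()) <= 1e-12).all()


class TestGammaFit:
    def test_exact_power_law_recovered_to_1e9(self):
        k = np.arange(1, 51)
        p = k ** -0.8
        p = p / p.sum()
        summary = topo.DegreeSummary(
            degrees=pd.Series(dtype=float),
            histogram=pd.Series(p, index=k),
            cumulative=pd.Series(p[::-1].cumsum()[::-1], index=k),
        )
        # normalization shifts the intercept only, not the slope
        assert topo.fit_gamma_loglog(summary) == pytest.approx(0.8, abs=1e-9)

    def test_single_support_point_is_error(self):
        with pytest.raises(ValueError):
            topo.fit_gamma_loglog(topo.degree_summary(nx.complete_graph(5)))

    def test_noisy_power_law_within_band(self):
        rng = np.random.default_rng(1)
        k = np.arange(1, 40)
        p = k ** -1.2 * np.exp(rng.normal(0, 0.05, size=k.size))
        p = p / p.sum()
        summary = topo.DegreeSummary(
            degrees=pd.Series(dtype=float),
            histogram=pd.Series(p, index=k),
            cumulative=pd.Series(p[::-1].cumsum()[::-1], index=k),
        )
        assert abs(topo.fit_gamma_loglog(summary) - 1.2) < 0.15


class TestCandidateFits:
    def test_poisson_degrees_best_fit_by_poisson(self):
        rng = np.random.default_rng(2)
        deg = pd.Series(rng.poisson(6, size=2000) + 1)
        summary = topo.DegreeSummary(degrees=deg, histogram=pd.Series(dtype=float),
                                     cumulative=pd.Series(dtype=float))
        table = topo.fit_candidate_distributions(summary)
        best = table.loc[table["is_best"], "distribution"].item()
        assert best in ("poisson", "negative_binomial")  # NB nests Poisson
        pois = table.set_index("distribution")
        assert pois.loc["poisson", "aic"] < pois.loc["power_law", "aic"]

    def test_zipf_degrees_best_fit_by_power_law(self):
        rng = np.random.default_rng(3)
        from scipy.stats import zipf
        deg = pd.Series(zipf.rvs(2.2, size=2000, random_state=rng))
        summary = topo.DegreeSummary(degrees=deg, histogram=pd.Series(dtype=float),
                                     cumulative=pd.Series(dtype=float))
        table = topo.fit_candidate_distributions(summary)
        assert table.loc[table["is_best"], "distribution"].item() == "power_law"

    def test_aic_is_definitional(self):
        rng = np.random.default_rng(4)
        deg = pd.Series(rng.poisson(4, size=100) + 1)
        summary = topo.DegreeSummary(degrees=deg, histogram=pd.Series(dtype=float),
                                     cumulative=pd.Series(dtype=float))
        table = topo.fit_candidate_distributions(summary)
        for _, row in table.dropna(subset=["aic"]).iterrows():
            assert row["aic"] == pytest.approx(
                2 * row["n_params"] - 2 * row["loglik"])


class TestKs:
    def test_identical_samples(self):
        d, p = topo.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_known_statistic(self):
        d, _ = topo.ks_two_sample([1, 1, 2], [2, 2, 3])
        assert d == pytest.approx(2 / 3)

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.integers(1, 10, 30)
        b = rng.integers(1, 10, 25)
        d1, _ = topo.ks_two_sample(a, b)
        d2, _ = topo.ks_two_sample(a ** 2 + 1, b ** 2 + 1)
        assert d1 == pytest.approx(d2)


class TestBasicMetrics:
    def test_transitivity_values(self):
        assert topo.transitivity(nx.complete_graph(3)) == 1.0
        assert topo.transitivity(nx.path_graph(3)) == 0.0
        k4_minus = nx.complete_graph(4)
        k4_minus.remove_edge(0, 1)
        assert topo.transitivity(k4_minus) == pytest.approx(0.75)

    def test_diameter_and_components(self):
        assert topo.diameter_and_components(nx.path_graph(5)) == (4, 1, 5)
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert topo.diameter_and_components(g) == (1, 2, 3)

    def test_diameter_matches_bfs_oracle(self):
        rng = np.random.default_rng(6)
        g = random_connected_graph(12, 0.3, rng)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        expected = max(max(d.values()) for d in lengths.values())
        assert topo.diameter_and_components(g)[0] == expected

    def test_edge_jaccard(self):
        g1 = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        g2 = nx.Graph([("b", "c"), ("c", "d"), ("d", "e")])
        assert topo.edge_jaccard(g1, g1) == 1.0
        assert topo.edge_jaccard(g1, g2) == pytest.approx(0.5)
        assert topo.edge_jaccard(nx.Graph([("a", "b")]),
                                 nx.Graph([("x", "y")])) == 0.0

    def test_edge_jaccard_empty_is_error(self):
        with pytest.raises(ValueError):
            topo.edge_jaccard(nx.Graph(), nx.Graph())


def _betweenness_oracle(g):
    """Exhaustive shortest-path enumeration (independent of networkx paths)."""
    nodes = list(g.nodes)
    adj = {n: set(g.neighbors(n)) for n in nodes}

    def all_paths(s, t):
        # BFS level structure, then count paths through DP
        import collections
        dist = {s: 0}
        q = collections.deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in adj[u]:
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    extend(path + [v])
        extend([s])
        return [p for p in paths if len(p) - 1 == dist[t]]

    btw = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for inner in p[1:-1]:
                btw[inner] += 1.0 / len(paths)
    return btw


class TestBetweenness:
    def test_path_center(self):
        b = topo.betweenness(nx.path_graph(3))
        assert b[1] == 1.0 and b[0] == 0.0 and b[2] == 0.0

    def test_star_center_counts_pairs(self):
        b = topo.betweenness(nx.star_graph(4))
        assert b[0] == math.comb(4, 2)

    def test_complete_graph_all_zero(self):
        assert (topo.betweenness(nx.complete_graph(6)) == 0).all()

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(8, 0.4, rng)
        expected = _betweenness_oracle(g)
        got = topo.betweenness(g)
        for n in g.nodes:
            assert got[n] == pytest.approx(expected[n], abs=1e-9)


class TestTopFraction:
    def test_distinct_scores_exact_count(self):
        scores = pd.Series(np.arange(20), index=[f"g{i}" for i in range(20)])
        assert len(topo.top_fraction(scores, 0.10)) == 2

    def test_total_tie_returns_all(self):
        scores = pd.Series(5.0, index=[f"g{i}" for i in range(10)])
        assert len(topo.top_fraction(scores, 0.10)) == 10

    def test_boundary_ties_included(self):
        scores = pd.Series([5, 5, 4, 3, 2, 2, 1, 1, 0, 0],
                           index=[f"g{i}" for i in range(10)])
        assert topo.top_fraction(scores, 0.10) == {"g0", "g1"}

    def test_at_least_ceil_fraction(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.random(37), index=[f"g{i}" for i in range(37)])
        assert len(topo.top_fraction(scores, 0.10)) >= math.ceil(0.10 * 37)


class TestSetComparison:
    def test_equal_sets_fully_shared(self):
        out = topo.compare_gene_sets({"a", "b"}, {"a", "b"})
        assert out["pct_shared"] == 100.0

    def test_disjoint_sets(self):
        out = topo.compare_gene_sets({"a"}, {"b"})
        assert out["pct_shared"] == 0.0

    def test_union_percentages(self):
        a = set(range(10))
        b = set(range(4, 14))
        out = topo.compare_gene_sets(a, b)
        assert out["n_shared"] == 6
        assert out["pct_shared"] == pytest.approx(100 * 6 / 14)
        assert out["n_shared"] + out["n_a_only"] + out["n_b_only"] == 14


class TestNeighborGain:
    def test_identical_networks_no_gain(self):
        g = nx.complete_graph(4)
        out = topo.neighbor_gain(g, g, [0, 1])
        assert all(len(v) == 0 for v in out["gains"].values())

    def test_gene_absent_in_a_gains_full_degree(self):
        ga = nx.Graph([("x", "y")])
        gb = nx.star_graph(5)
        out = topo.neighbor_gain(ga, gb, [0])
        assert len(out["gains"][0]) == 5

    def test_common_gained_is_intersection(self):
        ga = nx.Graph([("h1", "u"), ("h2", "u"), ("h3", "u")])
        gb = nx.Graph([("h1", "c"), ("h2", "c"), ("h3", "c"),
                       ("h1", "x"), ("h2", "y"), ("h3", "u"),
                       ("h1", "u"), ("h2", "u")])
        out = topo.neighbor_gain(ga, gb, ["h1", "h2", "h3"])
        assert out["common_gained"] == {"c"}

    def test_absent_from_both_is_error(self):
        with pytest.raises(KeyError):
            topo.neighbor_gain(nx.Graph([("a", "b")]),
                               nx.Graph([("a", "b")]), ["zz"])


class TestInducedSubgraph:
    def test_all_nodes_is_identity(self):
        g = nx.complete_graph(5)
        sub = topo.induced_subgraph(g, list(g.nodes))
        assert set(sub.graph.edges) == set(g.edges)

    def test_star_leaves_are_edgeless(self):
        g = nx.star_graph(4)
        sub = topo.induced_subgraph(g, [1, 2, 3, 4])
        assert sub.graph.number_of_edges() == 0

    def test_unknown_genes_dropped_with_count(self):
        g = nx.complete_graph(4)
        sub = topo.induced_subgraph(g, [0, 1, "nope"])
        assert sub.n_dropped == 1
        assert set(sub.graph.nodes) == {0, 1}


class TestRewiringNull:
    def test_degree_sequence_preserved_and_deterministic(self, barbell_graph):
        out1 = topo.rewiring_null(barbell_graph, n_replicates=5, seed=1)
        out2 = topo.rewiring_null(barbell_graph, n_replicates=5, seed=1)
        assert np.array_equal(out1["null_transitivity"],
                              out2["null_transitivity"])

    def test_planted_modularity_beats_null(self, benchmark_run):
        net = benchmark_run["A"]["net"]
        sub = topo.induced_subgraph(
            net, list(net.graph.nodes)[:200])
        out = topo.rewiring_null(sub, n_replicates=20, seed=2)
        assert out["observed_transitivity"] > \
            np.percentile(out["null_transitivity"], 95)

    def test_too_few_rewires_is_error(self, barbell_graph):
        with pytest.raises(ValueError):
            topo.rewiring_null(barbell_graph, n_rewires=3)
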