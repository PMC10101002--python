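import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fermnet import (
    AbundanceTable,
    TableError,
    build_network,
    detect_modules,
    summarize_network,
)
from fermnet.network import CooccurrenceNetwork
import networkx as nx


def _table(matrix):
    matrix = np.asarray(matrix, dtype=float)
    idx = [f"t{i}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=idx,
                      columns=[f"s{j}" for j in range(matrix.shape[1])])
    return AbundanceTable(df, pd.Series("bacteria", index=idx), False)


class TestBuildNetwork:
    def test_monotone_transform_gives_perfect_edge(self, rng):
        # relative table so compositional renormalization cannot distort
        # the planted monotone relationship
        x = np.linspace(0.05, 0.2, 20)
        y = x ** 2  # monotone transform of x
        filler = 1.0 - x - y
        df = pd.DataFrame(np.vstack([x, y, filler]),
                          index=[f"t{i}" for i in range(3)],
                          columns=[f"s{j}" for j in range(20)])
        t = AbundanceTable(df, pd.Series("bacteria", index=df.index), True)
        net = build_network(t, rho_min=0.8, p_max=0.01)
        assert net.graph.has_edge("t0", "t1")
        assert net.graph["t0"]["t1"]["rho"] == pytest.approx(1.0)

    def test_constant_taxon_warned_and_never_an_endpoint(self, rng):
        p = np.linspace(0.1, 0.7, 20)
        df = pd.DataFrame(np.vstack([np.full(20, 0.2), p, 0.8 - p]),
                          index=["t0", "t1", "t2"],
                          columns=[f"s{j}" for j in range(20)])
        t = AbundanceTable(df, pd.Series("bacteria", index=df.index), True)
        with pytest.warns(UserWarning, match="constant"):
            net = build_network(t, rho_min=0.5, p_max=0.5)
        assert net.graph.nodes["t0"]["excluded"]
        assert net.graph.degree("t0") == 0
        assert net.graph.has_edge("t1", "t2")  # perfect anti-correlation

    def test_edge_set_matches_bruteforce_spearman_bh_oracle(self, rng):
        X = rng.lognormal(0, 1, (20, 24))
        # plant a few strong monotone relationships
        X[1] = X[0] ** 2 * np.exp(rng.normal(0, 0.1, 24))
        X[3] = 1.0 / (X[2] + 0.5) * np.exp(rng.normal(0, 0.1, 24))
        t = _table(X)
        rho_min, p_max = 0.6, 0.05
        net = build_network(t, rho_min=rho_min, p_max=p_max)

        # brute force: scipy per-pair Spearman + step-up BH
        ra = t.relative_abundance().to_numpy()
        pairs, rhos, ps = [], [], []
        for i in range(20):
            for j in range(i + 1, 20):
                r, p = stats.spearmanr(ra[i], ra[j])
                pairs.append((f"t{i}", f"t{j}"))
                rhos.append(r)
                ps.append(p)
        ps = np.asarray(ps)
        n = len(ps)
        order = np.argsort(ps)
        adj = np.empty(n)
        ranked = ps[order] * n / (np.arange(n) + 1)
        adj[order] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1)
        expected = {
            frozenset(pair)
            for pair, r, q in zip(pairs, rhos, adj)
            if abs(r) >= rho_min and q <= p_max
        }
        got = {frozenset((u, v)) for u, v in net.graph.edges}
        assert got == expected

    def test_permutation_invariant_to_taxon_order(self, rng):
        X = rng.lognormal(0, 1, (8, 15))
        t = _table(X)
        net1 = build_network(t, rho_min=0.3, p_max=0.5)
        perm = rng.permutation(8)
        t2 = AbundanceTable(t.counts.iloc[perm], t.domain_of.iloc[perm], False)
        net2 = build_network(t2, rho_min=0.3, p_max=0.5)
        e1 = {frozenset(e) for e in net1.graph.edges}
        e2 = {frozenset(e) for e in net2.graph.edges}
        assert e1 == e2

    def test_no_thresholds_gives_complete_graph(self, rng):
        X = rng.lognormal(0, 1, (6, 12))
        net = build_network(_table(X), rho_min=0.0, p_max=1.0)
        assert net.n_edges == 6 * 5 // 2

    def test_too_few_samples_is_error(self, rng):
        with pytest.raises(TableError, match="4 samples"):
            build_network(_table(rng.random((5, 3))))


class TestDetectModules:
    def _net_from_graph(self, G):
        for v in G.nodes:
            G.nodes[v].setdefault("domain", "bacteria")
        return CooccurrenceNetwork(graph=G)

    def test_two_cliques_recovered_with_hand_computed_q(self):
        G = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    G.add_edge(base + i, base + j)
        G.add_edge(0, 5)  # single bridge
        net = detect_modules(self._net_from_graph(G), seed=0)
        mods = {frozenset(v for v, m in net.partition.items() if m == k)
                for k in set(net.partition.values())}
        assert mods == {frozenset(range(5)), frozenset(range(5, 10))}
        # Newman-Girvan Q for this partition on 21 edges:
        # each clique: e=10/21, degree sum=21 -> Q = 2*(10/21 - (21/42)^2)
        expected_q = 2 * (10 / 21 - 0.25)
        assert net.modularity == pytest.approx(expected_q, abs=1e-12)

    def test_complete_graph_single_module(self):
        net = detect_modules(self._net_from_graph(nx.complete_graph(6)), seed=0)
        assert len(set(net.partition.values())) == 1
        assert net.modularity == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_network_gives_singletons(self):
        G = nx.empty_graph(4)
        net = detect_modules(self._net_from_graph(G), seed=0)
        assert len(set(net.partition.values())) == 4
        assert net.modularity == 0.0

    def test_selected_q_is_max_over_algorithms(self, default_dataset):
        from fermnet import filter_taxa, merge_domains
        t = filter_taxa(merge_domains(default_dataset.bacteria,
                                      default_dataset.fungi))
        net = detect_modules(build_network(t), seed=0)
        assert net.modularity == pytest.approx(max(net.algorithm_q.values()))

    def test_modules_relabeled_by_decreasing_size(self):
        G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(6))
        net = detect_modules(self._net_from_graph(G), seed=0)
        sizes = pd.Series(net.partition).value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)
        assert sizes.index[0] == 0  # module 0 is the largest


class TestSummarizeNetwork:
    def test_triangle(self):
        G = nx.complete_graph(3)
        net = detect_modules(CooccurrenceNetwork(graph=G), seed=0)
        s = summarize_network(net)
        assert s.avg_clustering == pytest.approx(1.0)
        assert s.density == pytest.approx(1.0)

    def test_path_of_three(self):
        G = nx.path_graph(3)
        net = detect_modules(CooccurrenceNetwork(graph=G), seed=0)
        s = summarize_network(net)
        assert s.avg_clustering == pytest.approx(0.0)
        assert s.density == pytest.approx(2 / 3)

    def test_density_matches_recount(self, rng):
        G = nx.gnp_random_graph(30, 0.2, seed=7)
        net = detect_modules(CooccurrenceNetwork(graph=G), seed=0)
        s = summarize_network(net)
        n, e = G.number_of_nodes(), G.number_of_edges()
        assert s.density == pytest.approx(2 * e / (n * (n - 1)))
        assert s.n_nodes == n and s.n_edges == e
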