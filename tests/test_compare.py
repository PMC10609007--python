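"""Cross-group comparison: neighbor overlap, feature vectors, dendrograms."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparccnet as sn
from conftest import random_graph
from sparccnet.compare import (
    GroupNetworkSet,
    count_communities,
    edge_profile_vector,
    group_feature_vector,
    hierarchical_dendrogram,
    keystone_match_percent,
    neighbor_set,
)
from sparccnet.network import CentralityReport, CooccurrenceNetwork, analyze_network, build_network


def net_from_edges(nodes, edges):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w, abs_weight=abs(w))
    return CooccurrenceNetwork(graph=g, threshold=0.3)


def report_for(net, z=None):
    nodes = net.nodes
    z = z or {n: 0.0 for n in nodes}
    return CentralityReport(
        betweenness={n: 0.0 for n in nodes},
        z_value=z,
        community={n: 0 for n in nodes},
        keystone={n: z[n] > 2 for n in nodes},
        modularity=0.0,
    )


class TestNeighborSet:
    def test_star_center_sees_all_leaves(self):
        net = net_from_edges("cabde", [("c", x, 0.5) for x in "abde"])
        assert neighbor_set(net, "c") == set("abde")

    def test_isolated_node_empty(self):
        net = net_from_edges("abc", [("a", "b", 0.4)])
        assert neighbor_set(net, "c") == set()

    def test_unknown_taxon_rejected(self):
        net = net_from_edges("ab", [("a", "b", 0.4)])
        with pytest.raises(KeyError):
            neighbor_set(net, "zzz")

    def test_matches_edge_list_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            g = random_graph(rng)
            net = CooccurrenceNetwork(graph=g, threshold=0.0)
            for v in g.nodes:
                scan = {a if b == v else b for a, b in g.edges if v in (a, b)}
                assert neighbor_set(net, v) == scan


class TestKeystoneMatchPercent:
    def test_identical_neighbor_sets(self):
        net = net_from_edges(
            "abxyz", [("a", t, 0.5) for t in "xyz"] + [("b", t, 0.5) for t in "xyz"]
        )
        m = keystone_match_percent(net, "a", "b")
        assert m.percent == pytest.approx(100.0)

    def test_union_denominator_hand_case(self):
        # N(a) = {x, y, c}, N(b) = {y, z, w}: intersection {y}, union 5 -> 20%
        edges = [("a", t, 0.5) for t in ("x", "y", "c")] + [
            ("b", t, 0.5) for t in ("y", "z", "w")
        ]
        net = net_from_edges("abxyzcw", edges)
        m = keystone_match_percent(net, "a", "b")
        assert (m.intersection_size, m.union_size) == (1, 5)
        assert m.percent == pytest.approx(20.0)

    def test_min_denominator_variant(self):
        # N(a) = {p,q,r}, N(b) = {q,r,s}: union 50%, overlap coefficient 66.7%
        edges = [("a", t, 0.5) for t in "pqr"] + [("b", t, 0.5) for t in "qrs"]
        net = net_from_edges("abpqrs", edges)
        assert keystone_match_percent(net, "a", "b").percent == pytest.approx(50.0)
        m = keystone_match_percent(net, "a", "b", denominator="min")
        assert m.percent == pytest.approx(100 * 2 / 3)

    def test_symmetry_and_self_pair_rejection(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = random_graph(rng)
            net = CooccurrenceNetwork(graph=g, threshold=0.0)
            nodes = list(g.nodes)
            for a, b in itertools.combinations(nodes, 2):
                ma = keystone_match_percent(net, a, b).percent
                mb = keystone_match_percent(net, b, a).percent
                assert ma == pytest.approx(mb)
        with pytest.raises(ValueError):
            keystone_match_percent(net, nodes[0], nodes[0])

    def test_both_empty_flagged(self):
        net = net_from_edges("abc", [])
        m = keystone_match_percent(net, "a", "b")
        assert m.percent == 0.0 and m.both_empty


class TestFeatureVectors:
    def _net_set(self):
        nets = {
            "G1": net_from_edges("abc", [("a", "b", 0.7)]),
            "G2": net_from_edges("abc", [("a", "b", 0.7)]),
        }
        reps = {g: report_for(n) for g, n in nets.items()}
        return GroupNetworkSet(networks=nets, reports=reps)

    def test_edge_profile_reads_single_edge(self):
        ns = self._net_set()
        v = edge_profile_vector(ns, "a", "G1")
        expected = np.zeros(3)
        expected[ns.universe.index("b")] = 0.7
        np.testing.assert_allclose(v, expected)

    def test_identical_groups_identical_profiles(self):
        ns = self._net_set()
        np.testing.assert_allclose(
            edge_profile_vector(ns, "a", "G1"), edge_profile_vector(ns, "a", "G2")
        )

    def test_feature_vector_length(self):
        ns = self._net_set()
        v = group_feature_vector(ns, "G1")
        assert v.size == 3 + 3  # D + D(D-1)/2

    def test_identical_groups_identical_vectors(self):
        ns = self._net_set()
        np.testing.assert_allclose(
            group_feature_vector(ns, "G1"), group_feature_vector(ns, "G2")
        )

    def test_relabeling_preserves_pairwise_distances(self):
        rng = np.random.default_rng(13)
        rho = rng.uniform(-0.8, 0.8, size=(6, 6))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        rho2 = rho.copy()
        rho2[0, 1] = rho2[1, 0] = 0.0
        taxa = [f"t{i}" for i in range(6)]
        perm = [3, 1, 5, 0, 2, 4]
        taxa_p = [taxa[i] for i in perm]

        def vecs(order, mats):
            nets, reps = {}, {}
            for g, m in mats.items():
                nets[g], reps[g] = analyze_network(m, threshold=0.3, taxa=order)
            ns = GroupNetworkSet(networks=nets, reports=reps, universe=sorted(order))
            return {g: group_feature_vector(ns, g) for g in mats}

        mats = {"A": rho, "B": rho2}
        mats_p = {"A": rho[np.ix_(perm, perm)], "B": rho2[np.ix_(perm, perm)]}
        v1 = vecs(taxa, mats)
        v2 = vecs(taxa_p, mats_p)
        d1 = np.linalg.norm(v1["A"] - v1["B"])
        d2 = np.linalg.norm(v2["A"] - v2["B"])
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestDendrogram:
    def test_identical_vectors_merge_first_at_zero(self):
        vecs = {"A": np.array([1.0, 2.0]), "B": np.array([1.0, 2.0]), "C": np.array([9.0, 9.0])}
        tree = hierarchical_dendrogram(vecs)
        first = min(tree.merge_heights())
        assert first == pytest.approx(0.0)
        inner = tree.children[0] if tree.children[0].children else tree.children[1]
        assert sorted(inner.leaves) == ["A", "B"]

    def test_upgma_hand_computation(self):
        vecs = {"A": np.array([0.0]), "B": np.array([1.0]), "C": np.array([10.0])}
        tree = hierarchical_dendrogram(vecs, linkage="average")
        assert sorted(tree.merge_heights()) == pytest.approx([1.0, 9.5])

    def test_order_invariance(self):
        rng = np.random.default_rng(17)
        base = {g: rng.normal(size=4) for g in "ABCDE"}
        ref = hierarchical_dendrogram(base).to_newick()
        for perm in itertools.permutations("ABCDE"):
            shuffled = {g: base[g] for g in perm}
            assert hierarchical_dendrogram(shuffled).to_newick() == ref

    def test_merge_heights_monotone_along_root_paths(self):
        rng = np.random.default_rng(19)
        vecs = {f"g{i}": rng.normal(size=6) for i in range(6)}
        tree = hierarchical_dendrogram(vecs)

        def check(node):
            if node.children is None:
                return
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree)

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        rng = np.random.default_rng(23)
        vecs = {f"g{i}": rng.normal(size=5) for i in range(6)}
        tree = hierarchical_dendrogram(vecs, linkage="average")
        X = np.array([vecs[f"g{i}"] for i in range(6)])
        heights = sorted(scipy_linkage(X, method="average")[:, 2])
        assert sorted(tree.merge_heights()) == pytest.approx(heights)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_dendrogram({"A": np.zeros(2), "B": np.zeros(3)})


class TestCountCommunities:
    def test_single_label(self):
        rep = report_for(net_from_edges("abc", [("a", "b", 0.5)]))
        assert count_communities(rep) == 1

    def test_edgeless_graph_singletons(self):
        net = net_from_edges("abcde", [])
        rep = report_for(net)
        rep.community = {n: i for i, n in enumerate("abcde")}
        assert count_communities(rep) == 5

    def test_displayed_subset_scope(self):
        net = net_from_edges("abcde", [])
        rep = report_for(net, z={"a": 3.0, "b": 0.0, "c": 0.0, "d": 0.0, "e": 0.0})
        rep.community = {"a": 0, "b": 1, "c": 1, "d": 2, "e": 3}
        abund = {"a": 0.01, "b": 0.5, "c": 0.3, "d": 0.1, "e": 0.05}
        # top-2 by abundance = {b, c} (community 1) plus keystone a (community 0)
        assert count_communities(rep, "displayed_subset", abund, rank_cutoff=2) == 2

    def test_planted_three_block_recovery(self):
        hits = 0
        for seed in range(10):
            b = sn.plant_correlation_network(24, 3, hub_count=0, within_rho=0.75, seed=seed)
            table, _ = sn.simulate_count_table(b, n_per_group=120, depth=20_000, seed=500 + seed)
            est = sn.sparcc_estimate(table, n_resamples=5, seed=seed)
            _, rep = analyze_network(est, threshold=0.3, seed=seed)
            hits += rep.n_communities() == 3
        assert hits >= 8  # >= 80% of seeds
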