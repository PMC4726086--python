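import itertools
import math
import random

import networkx as nx
import numpy as np
import pytest

from bacnet.io_formats import EdgeRecord
from bacnet.network import (
    PPINetwork,
    merge_networks,
    powerlaw_gamma_mle,
    remove_self_loops,
    rewire_preserving_degrees,
    topology_summary,
)
from conftest import net_from_pairs


def records(pairs):
    return [EdgeRecord(a, b) for a, b in pairs]


class TestMerge:
    def test_union_and_shared_counts(self):
        net, rep = merge_networks(
            records([("a", "b"), ("c", "d")]),
            records([("c", "d"), ("e", "f")]),
        )
        assert (rep.n_channel_a, rep.n_channel_b, rep.n_shared, rep.n_union) == (
            2, 2, 1, 3,
        )

    def test_disjoint_channels(self):
        a = records([(f"a{i}", f"b{i}") for i in range(5)])
        b = records([(f"c{i}", f"d{i}") for i in range(7)])
        _, rep = merge_networks(a, b)
        assert rep.n_shared == 0 and rep.n_union == 12

    def test_identical_channels(self):
        a = records([("a", "b"), ("c", "d")])
        _, rep = merge_networks(a, a)
        assert rep.n_shared == 2 and rep.n_union == 2

    def test_remerge_is_idempotent(self):
        a = records([("a", "b"), ("c", "d")])
        b = records([("c", "d"), ("e", "f")])
        merged, _ = merge_networks(a, b)
        again, rep = merge_networks(merged.records(), b)
        assert again.edges == merged.edges
        assert rep.n_union == merged.n_edges

    def test_evidence_tags_merge_per_edge(self):
        a = [EdgeRecord("a", "b", {"interolog"}, ["X"])]
        b = [EdgeRecord("a", "b", {"ddi"}, ["PF1|PF2"])]
        net, rep = merge_networks(a, b)
        assert rep.n_shared == 1
        assert net.record("a", "b").evidence == {"interolog", "ddi"}


class TestSelfLoops:
    def test_loop_removed_nodes_kept_if_connected(self):
        net = net_from_pairs([("a", "a"), ("a", "b")])
        out, rep = remove_self_loops(net)
        assert out.edges == {("a", "b")}
        assert rep.n_self_loops_removed == 1 and rep.n_nodes_dropped == 0

    def test_isolated_loop_node_dropped(self):
        out, rep = remove_self_loops(net_from_pairs([("a", "a")]))
        assert out.n_nodes == 0 and rep.n_nodes_dropped == 1

    def test_identity_when_no_loops(self, triangle):
        out, rep = remove_self_loops(triangle)
        assert out == triangle and rep.n_self_loops_removed == 0


class TestTopology:
    def test_triangle(self, triangle):
        s = topology_summary(triangle)
        assert s.clustering_coefficient == pytest.approx(1.0)
        assert s.average_path_length == pytest.approx(1.0)
        assert s.n_components == 1

    def test_path_of_three(self, path3):
        s = topology_summary(path3)
        assert s.average_degree == pytest.approx(4 / 3)
        assert s.clustering_coefficient == pytest.approx(0.0)
        # ordered pairs: (a,b)=1 (b,c)=1 (a,c)=2 -> mean 4/3
        assert s.average_path_length == pytest.approx(4 / 3)

    def test_two_disjoint_edges(self):
        s = topology_summary(net_from_pairs([("a", "b"), ("c", "d")]))
        assert s.n_components == 2
        assert s.average_path_length == pytest.approx(1.0)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            topology_summary(PPINetwork())

    def test_agrees_with_floyd_warshall_and_triangle_enumeration(self):
        rng = random.Random(5)
        for trial in range(15):
            n = rng.randint(4, 30)
            p = rng.uniform(0.1, 0.5)
            g = nx.gnp_random_graph(n, p, seed=rng.randrange(10**6))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            net = PPINetwork.from_graph(g)
            s = topology_summary(net)

            # Floyd–Warshall oracle
            nodes = sorted(g.nodes)
            dist = {
                (u, v): (0 if u == v else (1 if g.has_edge(u, v) else math.inf))
                for u in nodes
                for v in nodes
            }
            for k in nodes:
                for i in nodes:
                    for j in nodes:
                        alt = dist[i, k] + dist[k, j]
                        if alt < dist[i, j]:
                            dist[i, j] = alt
            finite = [
                d for (u, v), d in dist.items() if u != v and math.isfinite(d)
            ]
            if finite:
                assert s.average_path_length == pytest.approx(
                    sum(finite) / len(finite)
                )

            # triangle-enumeration oracle for clustering
            cc = {}
            for v in nodes:
                nb = sorted(g.neighbors(v))
                d = len(nb)
                if d < 2:
                    cc[v] = 0.0
                    continue
                tri = sum(
                    1 for x, y in itertools.combinations(nb, 2) if g.has_edge(x, y)
                )
                cc[v] = 2 * tri / (d * (d - 1))
            eligible = [cc[v] for v in nodes if g.degree(v) >= 2]
            if eligible:
                assert s.clustering_coefficient == pytest.approx(
                    sum(eligible) / len(eligible)
                )
            for v in nodes:
                assert s.per_node[v].clustering == pytest.approx(cc[v])


class TestPowerLaw:
    def test_closed_form_on_tiny_sample(self):
        fit = powerlaw_gamma_mle([1, 1, 1, 2, 4], k_min=1)
        expected = 1 + 5 / (math.log(2) + math.log(4))
        assert fit.gamma == pytest.approx(expected)
        assert fit.n_tail == 5

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_gamma_mle([3, 3], k_min=3)

    def test_k_min_restricts_the_tail(self):
        fit = powerlaw_gamma_mle([1, 1, 2, 3, 8], k_min=2)
        assert fit.n_tail == 3


class TestRewiring:
    def test_degree_sequence_preserved(self, default_world):
        net, _ = remove_self_loops(default_world.truth_network)
        rewired = rewire_preserving_degrees(net, seed=3)
        before = sorted(d for _, d in net.graph.degree())
        after = sorted(d for _, d in rewired.graph.degree())
        assert before == after
        assert {d for _, d in net.graph.degree()} == {
            d for _, d in rewired.graph.degree()
        }
        # per-node degrees, not just the sequence
        for node in net.nodes:
            assert net.graph.degree(node) == rewired.graph.degree(node)

    def test_triangle_has_no_legal_swap(self, triangle):
        assert rewire_preserving_degrees(triangle, seed=0) == triangle

    def test_seed_determinism_and_variation(self):
        g = nx.gnm_random_graph(40, 100, seed=9)
        net = PPINetwork.from_graph(
            nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        )
        r1 = rewire_preserving_degrees(net, seed=1)
        r2 = rewire_preserving_degrees(net, seed=1)
        r3 = rewire_preserving_degrees(net, seed=2)
        assert r1 == r2
        assert r1 != r3

    def test_no_self_loops_or_duplicates_introduced(self):
        g = nx.gnm_random_graph(25, 60, seed=4)
        net = PPINetwork.from_graph(
            nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        )
        rewired = rewire_preserving_degrees(net, seed=0)
        assert all(a != b for a, b in rewired.edges)
        assert len(rewired.edges) == net.n_edges
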