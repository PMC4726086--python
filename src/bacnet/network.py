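"""The merged PPI network and its topological characterization.

The network is an undirected simple graph over protein identifiers,
backed by :mod:`networkx`.  Topology conventions follow the
NetworkAnalyzer tool tradition: the average shortest-path length is the
mean over connected ordered pairs only (so it is defined on disconnected
graphs), the network clustering coefficient averages over nodes of degree
>= 2, and closeness of a node is the number of other reachable nodes
divided by the sum of their distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import optimize, special

from .io_formats import EdgeRecord, canonical_pair, merge_edge_records


class PPINetwork:
    """Undirected simple graph over protein ids with per-edge evidence."""

    def __init__(self, records: Iterable[EdgeRecord] = ()) -> None:
        self.graph = nx.Graph()
        self.add_records(records)

    # -- construction -----------------------------------------------------
    def add_records(self, records: Iterable[EdgeRecord]) -> None:
        for rec in merge_edge_records(records):
            self.add_record(rec)

    def add_record(self, rec: EdgeRecord) -> None:
        a, b = rec.pair
        if self.graph.has_edge(a, b):
            existing: EdgeRecord = self.graph.edges[a, b]["record"]
            existing.evidence |= rec.evidence
            for src in rec.sources:
                if src not in existing.sources:
                    existing.sources.append(src)
        else:
            self.graph.add_edge(
                a, b, record=EdgeRecord(a, b, set(rec.evidence), list(rec.sources))
            )

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "PPINetwork":
        net = cls()
        for u, v, data in graph.edges(data=True):
            rec = data.get("record")
            if rec is None:
                rec = EdgeRecord(u, v)
            net.add_record(rec)
        for node in graph.nodes:
            net.graph.add_node(node)
        return net

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_pair(u, v) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def records(self) -> list[EdgeRecord]:
        return sorted(
            (data["record"] for _, _, data in self.graph.edges(data=True)),
            key=lambda r: r.pair,
        )

    def record(self, a: str, b: str) -> EdgeRecord:
        return self.graph.edges[a, b]["record"]

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def subgraph(self, nodes: Iterable[str]) -> "PPINetwork":
        return PPINetwork.from_graph(self.graph.subgraph(list(nodes)).copy())

    def copy(self) -> "PPINetwork":
        return PPINetwork.from_graph(self.graph.copy())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.graph.has_edge(*pair)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class MergeReport:
    n_channel_a: int
    n_channel_b: int
    n_shared: int
    n_union: int


def merge_networks(
    channel_a: Sequence[EdgeRecord], channel_b: Sequence[EdgeRecord]
) -> tuple[PPINetwork, MergeReport]:
    """Union of two evidence channels into one non-redundant network."""
    a = merge_edge_records(channel_a)
    b = merge_edge_records(channel_b)
    pairs_a = {r.pair for r in a}
    pairs_b = {r.pair for r in b}
    net = PPINetwork(a)
    net.add_records(b)
    report = MergeReport(
        n_channel_a=len(pairs_a),
        n_channel_b=len(pairs_b),
        n_shared=len(pairs_a & pairs_b),
        n_union=net.n_edges,
    )
    assert report.n_union == report.n_channel_a + report.n_channel_b - report.n_shared
    return net, report


@dataclass
class SelfLoopReport:
    n_self_loops_removed: int
    n_nodes_dropped: int


def remove_self_loops(network: PPINetwork) -> tuple[PPINetwork, SelfLoopReport]:
    """Drop homomeric edges and any nodes they leave isolated."""
    g = network.graph.copy()
    loops = list(nx.selfloop_edges(g))
    g.remove_edges_from(loops)
    orphans = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(orphans)
    return PPINetwork.from_graph(g), SelfLoopReport(
        n_self_loops_removed=len(loops), n_nodes_dropped=len(orphans)
    )


@dataclass
class NodeMetrics:
    degree: int
    clustering: float
    avg_shortest_path: float
    betweenness: float
    closeness: float


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    clustering_coefficient: float
    n_components: int
    largest_component_nodes: int
    largest_component_edges: int
    per_node: dict[str, NodeMetrics] = field(default_factory=dict)


def topology_summary(
    network: PPINetwork, include_degree_one_in_clustering: bool = False
) -> TopologySummary:
    """Compute global and per-node topology statistics.

    Intended to run on the self-loop-free network.  The average path
    length averages shortest-path distances over all connected ordered
    pairs; betweenness is normalized by (n-1)(n-2)/2 over the whole graph.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("topology_summary on an empty network")

    degree = dict(g.degree())
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)

    path_sum = 0.0
    path_pairs = 0
    avg_sp: dict[str, float] = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        total = sum(lengths.values())
        reach = len(lengths) - 1  # exclude the node itself
        avg_sp[node] = total / reach if reach else 0.0
        path_sum += total
        path_pairs += reach

    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    largest_edges = g.subgraph(largest).number_of_edges()

    if include_degree_one_in_clustering:
        cc_values = list(clustering.values())
    else:
        cc_values = [clustering[n] for n in g.nodes if degree[n] >= 2]
    network_clustering = float(np.mean(cc_values)) if cc_values else 0.0

    per_node = {
        n: NodeMetrics(
            degree=degree[n],
            clustering=clustering[n],
            avg_shortest_path=avg_sp[n],
            betweenness=betweenness[n],
            closeness=closeness[n],
        )
        for n in g.nodes
    }

    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        average_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        average_path_length=path_sum / path_pairs if path_pairs else 0.0,
        clustering_coefficient=network_clustering,
        n_components=len(components),
        largest_component_nodes=len(largest),
        largest_component_edges=largest_edges,
        per_node=per_node,
    )


@dataclass
class PowerLawFit:
    """Degree-exponent estimates for a scale-free degree distribution.

    ``gamma`` is the continuous-approximation closed-form MLE
    1 + n / sum(ln(k_i / k_min)); ``gamma_discrete`` numerically maximizes
    the discrete (Hurwitz-zeta) likelihood.  Both are reported side by side.
    """

    gamma: float
    gamma_discrete: float
    k_min: int
    n_tail: int

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("power-law exponent must exceed 1")


def powerlaw_gamma_mle(degrees: Sequence[int], k_min: int = 1) -> PowerLawFit:
    """Maximum-likelihood degree exponent for degrees >= k_min."""
    tail = np.asarray([k for k in degrees if k >= k_min], dtype=float)
    if tail.size < 2 or len(set(tail.tolist())) < 2:
        raise ValueError("need >=2 distinct degree values >= k_min")
    log_sum = float(np.sum(np.log(tail / k_min)))
    if log_sum <= 0:
        raise ValueError("all degrees equal k_min; exponent undefined")
    n = tail.size
    gamma_cont = 1.0 + n / log_sum

    sum_log = float(np.sum(np.log(tail)))
    res = optimize.minimize_scalar(
        lambda g: n * math.log(special.zeta(g, k_min)) + g * sum_log,
        bounds=(1.0001, 12.0),
        method="bounded",
    )
    return PowerLawFit(
        gamma=gamma_cont,
        gamma_discrete=float(res.x),
        k_min=k_min,
        n_tail=int(n),
    )


def sample_powerlaw_degrees(
    gamma: float, n: int, k_min: int = 1, seed: int = 0
) -> np.ndarray:
    """Draw integer degrees k >= k_min with P(k) ∝ k^-gamma (zeta law).

    Sampling rejects zeta variates below k_min, so the support is exactly
    {k_min, k_min+1, ...} with the Hurwitz-zeta normalization.  The
    matching estimator is the discrete (``gamma_discrete``) MLE; the
    continuous closed form is biased at small k_min on genuinely discrete
    data.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    out = np.empty(0, dtype=int)
    while out.size < n:
        draw = stats.zipf.rvs(gamma, size=2 * n, random_state=rng)
        out = np.concatenate([out, draw[draw >= k_min]])
    return out[:n].astype(int)


def rewire_preserving_degrees(
    network: PPINetwork,
    n_swaps: int | None = None,
    seed: int = 0,
) -> PPINetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Two edges (a, b) and (c, d) are chosen uniformly and replaced by
    (a, d) and (c, b); swaps creating self-loops or duplicate edges are
    rejected.  Deterministic for a fixed seed.  Default n_swaps is
    10 * |edges|; attempts are capped at 10x that so graphs with no legal
    swap (e.g. a triangle) still terminate.
    """
    edges = sorted(network.edges)
    if len(edges) < 2:
        return network.copy()
    if n_swaps is None:
        n_swaps = 10 * len(edges)

    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    edge_list = list(edges)
    successes = 0
    attempts = 0
    max_attempts = 10 * n_swaps + 100
    while successes < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edge_list), size=2)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        # randomize orientation of the second edge
        if rng.random() < 0.5:
            c, d = d, c
        new1 = canonical_pair(a, d)
        new2 = canonical_pair(c, b)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        if new1 in edge_set or new2 in edge_set or new1 == new2:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[i] = new1
        edge_list[j] = new2
        successes += 1

    rewired = PPINetwork(EdgeRecord(a, b) for a, b in sorted(edge_set))
    for node in network.nodes:
        rewired.graph.add_node(node)
    return rewired


def configuration_model_null(network: PPINetwork, seed: int = 0) -> PPINetwork:
    """Configuration-model alternative null (parallel edges and loops
    collapsed, so degrees are only approximately preserved)."""
    degseq = [d for _, d in network.graph.degree()]
    g = nx.configuration_model(degseq, seed=seed)
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    mapping = dict(enumerate(sorted(network.nodes)))
    g = nx.relabel_nodes(g, mapping)
    return PPINetwork.from_graph(g)
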