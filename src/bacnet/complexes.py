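"""Protein complex detection on time-series active subnetworks.

Complexes are mined per time point from the expression-filtered network
with a greedy density clustering: clusters grow from high-degree seeds
by absorbing the neighbor best connected to the current cluster, as long
as its connectivity stays above lambda * |cluster| / 2.  Clusters found
at different time points that overlap strongly (overlap score
|A∩B|² / (|A|·|B|) >= 0.8) are merged.  This is a fully specified,
deterministic stand-in for time-series-network complex discovery
algorithms; it shares their interface (interactions + expression in,
parameters: RPKM threshold, lambda, minimum size) but is not a bit-exact
reimplementation of any published method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet, ExpressionMatrix
from .network import PPINetwork
from .dynamics import ConditionNetwork, active_subnetwork
from .enrichment import ComplexEntropy, functional_entropy

DEFAULT_MERGE_OVERLAP = 0.8


@dataclass
class ComplexSet:
    complexes: list[list[str]]  # each sorted member list
    provenance: list[set[str]]  # contributing time labels per complex
    rpkm_threshold: float = 1.0
    lam: float = 1.0
    min_size: int = 3


def build_time_series_networks(
    base: PPINetwork,
    expression: ExpressionMatrix,
    threshold: float = 1.0,
) -> list[ConditionNetwork]:
    """One expression-filtered subnetwork per time point."""
    return [
        active_subnetwork(base, expression, label, threshold)
        for label in expression.time_labels
    ]


def _cluster_one_network(
    network: PPINetwork, lam: float, min_size: int
) -> list[list[str]]:
    g = network.graph
    degree = dict(g.degree())
    unassigned = set(g.nodes)
    clusters: list[list[str]] = []
    # seeds in decreasing degree, lexicographic tie-break
    order = sorted(g.nodes, key=lambda v: (-degree[v], v))
    for seed in order:
        if seed not in unassigned:
            continue
        cluster = {seed}
        frontier = (set(g.neighbors(seed)) & unassigned) - cluster
        while frontier:
            links = {
                u: sum(1 for w in g.neighbors(u) if w in cluster)
                for u in frontier
            }
            best = min(frontier, key=lambda u: (-links[u], -degree[u], u))
            if links[best] < lam * len(cluster) / 2.0:
                break
            cluster.add(best)
            frontier.discard(best)
            frontier |= (set(g.neighbors(best)) & unassigned) - cluster
        if len(cluster) >= min_size:
            clusters.append(sorted(cluster))
            unassigned -= cluster
        else:
            unassigned.discard(seed)
    return clusters


def overlap_score(a: set[str], b: set[str]) -> float:
    """Neighborhood-affinity overlap: |A∩B|² / (|A|·|B|)."""
    inter = len(a & b)
    if not a or not b:
        return 0.0
    return inter * inter / (len(a) * len(b))


def detect_complexes(
    tsn: list[ConditionNetwork],
    lam: float = 1.0,
    min_size: int = 3,
    merge_overlap: float = DEFAULT_MERGE_OVERLAP,
) -> ComplexSet:
    """Greedy density clustering per time point, then cross-time merging.

    Deterministic: seeds are taken in decreasing-degree order with
    lexicographic tie-breaks, candidate absorption prefers more links to
    the cluster, then higher degree, then the lexicographically smaller
    id.  Merging unions any two clusters whose overlap score reaches
    ``merge_overlap`` until no pair qualifies.
    """
    if not tsn:
        raise ValueError("need at least one time-series subnetwork")
    raw: list[tuple[set[str], set[str]]] = []  # (members, time labels)
    for cond in tsn:
        for members in _cluster_one_network(cond.network, lam, min_size):
            raw.append((set(members), {cond.time_label}))

    # iterated pairwise merging to a fixpoint, deterministic order
    merged = True
    while merged:
        merged = False
        raw.sort(key=lambda item: sorted(item[0]))
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                if overlap_score(raw[i][0], raw[j][0]) >= merge_overlap:
                    members = raw[i][0] | raw[j][0]
                    labels = raw[i][1] | raw[j][1]
                    raw[i] = (members, labels)
                    del raw[j]
                    merged = True
                    break
            if merged:
                break

    raw.sort(key=lambda item: (-len(item[0]), sorted(item[0])))
    return ComplexSet(
        complexes=[sorted(members) for members, _ in raw],
        provenance=[labels for _, labels in raw],
        lam=lam,
        min_size=min_size,
        rpkm_threshold=tsn[0].threshold,
    )


@dataclass
class ComplexScoreSummary:
    entropies: list[ComplexEntropy]
    median_entropy: float
    low_entropy_fraction: float  # fraction of complexes with entropy < 1 bit


def score_complexes(
    complex_set: ComplexSet, annotations: AnnotationSet
) -> ComplexScoreSummary:
    """Functional-category entropy per complex plus distribution summary."""
    entropies = [
        functional_entropy(members, annotations, complex_id=f"C{i + 1}")
        for i, members in enumerate(complex_set.complexes)
    ]
    values = [e.entropy for e in entropies]
    if values:
        median = float(np.median(values))
        low_frac = sum(1 for v in values if v < 1.0) / len(values)
    else:
        median, low_frac = float("nan"), float("nan")
    return ComplexScoreSummary(
        entropies=entropies,
        median_entropy=median,
        low_entropy_fraction=low_frac,
    )
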