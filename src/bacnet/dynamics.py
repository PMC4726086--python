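"""Condition-specific subnetworks and transcription-difference analysis.

A gene whose RPKM falls below 1 at a time point is treated as inactive
and removed from the network together with its edges, yielding one
condition network per time point.  Conditions are compared through five
node-level topology metrics and through the normalized transcription
difference D_ij = |RPKM_i - RPKM_j| / (RPKM_i + RPKM_j), a scale-free
dissimilarity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_formats import AnnotationSet, ExpressionMatrix
from .network import PPINetwork, topology_summary
from .validation import TestReport, wilcoxon_rank_sum

TOPOLOGY_METRICS = (
    "degree",
    "clustering",
    "avg_shortest_path",
    "betweenness",
    "closeness",
)


@dataclass
class ConditionNetwork:
    base: PPINetwork
    time_label: str
    active_nodes: set[str]
    network: PPINetwork
    threshold: float = 1.0


@dataclass
class DifferenceDistribution:
    group: str  # "control" | "all_ppi" | "category:<letter>"
    time_label: str
    values: list[float]
    median: float = float("nan")
    empty: bool = False

    def __post_init__(self) -> None:
        if self.values:
            self.median = float(np.median(self.values))
        else:
            self.empty = True


def active_subnetwork(
    base: PPINetwork,
    expression: ExpressionMatrix,
    time_label: str,
    threshold: float = 1.0,
) -> ConditionNetwork:
    """Induced subgraph on nodes expressed (RPKM >= threshold) at a time point.

    Nodes missing from the expression matrix are treated as inactive.
    """
    t = expression.time_index(time_label)  # raises KeyError when unknown
    active = {
        v
        for v in base.nodes
        if v in expression.rpkm and expression.rpkm[v][t] >= threshold
    }
    return ConditionNetwork(
        base=base,
        time_label=time_label,
        active_nodes=active,
        network=base.subgraph(active),
        threshold=threshold,
    )


def normalized_difference(rpkm_i: float, rpkm_j: float) -> float:
    """|RPKM_i - RPKM_j| / (RPKM_i + RPKM_j); symmetric, scale-invariant."""
    total = rpkm_i + rpkm_j
    if total <= 0:
        raise ValueError("normalized difference undefined for two zero RPKMs")
    return abs(rpkm_i - rpkm_j) / total


def difference_distributions(
    condition: ConditionNetwork,
    expression: ExpressionMatrix,
    annotations: AnnotationSet | None = None,
    groups: list[str] = ("control", "all_ppi"),
    max_control_pairs: int = 1_000_000,
    seed: int = 0,
) -> list[DifferenceDistribution]:
    """Normalized-difference distributions for the requested pair groups.

    control: all unordered active-node pairs (seeded subsample above
    ``max_control_pairs``); all_ppi: edges of the condition network;
    category:<X>: edges whose two endpoints both carry COG letter X.
    """
    t = expression.time_index(condition.time_label)
    value = {v: float(expression.rpkm[v][t]) for v in condition.active_nodes}

    out: list[DifferenceDistribution] = []
    for group in groups:
        if group == "control":
            nodes = sorted(condition.active_nodes)
            n = len(nodes)
            total_pairs = n * (n - 1) // 2
            if total_pairs > max_control_pairs:
                rng = np.random.default_rng(seed)
                vals = []
                while len(vals) < max_control_pairs:
                    i, j = rng.integers(0, n, size=2)
                    if i == j:
                        continue
                    vals.append(
                        normalized_difference(value[nodes[i]], value[nodes[j]])
                    )
            else:
                vals = [
                    normalized_difference(value[a], value[b])
                    for a, b in combinations(nodes, 2)
                ]
        elif group == "all_ppi":
            vals = [
                normalized_difference(value[a], value[b])
                for a, b in sorted(condition.network.edges)
                if a != b
            ]
        elif group.startswith("category:"):
            letter = group.split(":", 1)[1]
            if annotations is None:
                raise ValueError("category groups require annotations")
            vals = [
                normalized_difference(value[a], value[b])
                for a, b in sorted(condition.network.edges)
                if a != b
                and letter in annotations.cog.get(a, [])
                and letter in annotations.cog.get(b, [])
            ]
        else:
            raise ValueError(f"unknown group {group!r}")
        out.append(
            DifferenceDistribution(
                group=group, time_label=condition.time_label, values=vals
            )
        )
    return out


def compare_local_topology(
    conditions: list[ConditionNetwork],
) -> dict[str, dict[tuple[str, str], TestReport]]:
    """Pairwise two-sided Wilcoxon tests on five node-level metrics.

    Conditions with fewer than 3 active nodes are excluded (reported via
    the returned key set simply lacking them).
    """
    usable = [c for c in conditions if c.network.n_nodes >= 3]
    if len(usable) < 2:
        raise ValueError("need >=2 conditions with >=3 nodes each")

    metric_values: dict[str, dict[str, list[float]]] = {
        m: {} for m in TOPOLOGY_METRICS
    }
    for cond in usable:
        summary = topology_summary(cond.network)
        for metric in TOPOLOGY_METRICS:
            metric_values[metric][cond.time_label] = [
                getattr(nm, metric) for nm in summary.per_node.values()
            ]

    reports: dict[str, dict[tuple[str, str], TestReport]] = {}
    for metric in TOPOLOGY_METRICS:
        reports[metric] = {}
        for c1, c2 in combinations(usable, 2):
            x = metric_values[metric][c1.time_label]
            y = metric_values[metric][c2.time_label]
            reports[metric][(c1.time_label, c2.time_label)] = wilcoxon_rank_sum(
                x, y, alternative="two-sided"
            )
    return reports
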