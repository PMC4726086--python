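"""Recompute the headline statistics of a published interactome edge list.

Given a merged PPI edge list (for example a supplementary network table
of a published study), this module recomputes the numbers such papers
print: node/edge counts before and after removing homomeric
interactions, average degree, average path length (connected-pairs
convention), clustering coefficient (degree >= 2 convention), component
counts, largest-component sizes, the maximum-likelihood degree exponent
and the minimum dominating set size.
"""

from __future__ import annotations

from .io_formats import read_edge_list
from .mds import solve_mds_ilp
from .network import (
    PPINetwork,
    powerlaw_gamma_mle,
    remove_self_loops,
    topology_summary,
)


def published_network_report(
    path,
    mds_time_limit: float | None = 1800.0,
    include_mds: bool = True,
) -> dict:
    """Full characterization of an edge-list network file."""
    records = read_edge_list(path)
    full = PPINetwork(records)
    reduced, loop_report = remove_self_loops(full)
    summary = topology_summary(reduced)
    degrees = [m.degree for m in summary.per_node.values()]
    fit = powerlaw_gamma_mle(degrees)

    report = {
        "full_nodes": full.n_nodes,
        "full_edges": full.n_edges,
        "self_loops_removed": loop_report.n_self_loops_removed,
        "reduced_nodes": reduced.n_nodes,
        "reduced_edges": reduced.n_edges,
        "average_degree": summary.average_degree,
        "average_path_length": summary.average_path_length,
        "clustering_coefficient": summary.clustering_coefficient,
        "n_components": summary.n_components,
        "largest_component_nodes": summary.largest_component_nodes,
        "largest_component_edges": summary.largest_component_edges,
        "gamma_continuous": fit.gamma,
        "gamma_discrete": fit.gamma_discrete,
    }
    if include_mds:
        # the MDS of the full network (isolated self-loop nodes dominate
        # themselves) and of the reduced one are both of interest
        mds_full = solve_mds_ilp(full, time_limit=mds_time_limit)
        mds_reduced = solve_mds_ilp(reduced, time_limit=mds_time_limit)
        report["mds_size_full"] = mds_full.size
        report["mds_full_optimal"] = mds_full.optimal
        report["mds_size_reduced"] = mds_reduced.size
        report["mds_reduced_optimal"] = mds_reduced.optimal
    return report
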