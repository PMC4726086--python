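"""Minimum dominating set computation for network controllability.

Domination is closed-neighborhood: a node dominates itself and its
neighbors, so an isolated node can only be dominated by selecting it.
The exact solver formulates the standard integer program

    minimize   sum_v x_v
    subject to x_v + sum_{u in N(v)} x_u >= 1   for every node v
               x_v in {0, 1}

and solves it to proven optimality with the HiGHS branch-and-bound MILP
solver.  An exhaustive enumerator (small graphs) and the classic greedy
ln-n approximation are provided as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import PPINetwork


@dataclass
class MDSResult:
    members: set[str]
    size: int
    method: str  # ilp | greedy | exhaustive
    optimal: bool

    def __post_init__(self) -> None:
        if self.size != len(self.members):
            raise ValueError("size must equal |members|")


def verify_dominating(network: PPINetwork, members: set[str]) -> bool:
    """True iff every node is in ``members`` or adjacent to one."""
    unknown = members - network.nodes
    if unknown:
        raise ValueError(f"unknown node id(s) in members: {sorted(unknown)}")
    for node in network.nodes:
        if node in members:
            continue
        if not (network.neighbors(node) & members):
            return False
    return True


def solve_mds_ilp(network: PPINetwork, time_limit: float | None = None) -> MDSResult:
    """Exact minimum dominating set via integer linear programming."""
    nodes = sorted(network.nodes)
    n = len(nodes)
    if n == 0:
        return MDSResult(set(), 0, "ilp", True)
    index = {v: i for i, v in enumerate(nodes)}

    rows, cols = [], []
    for v in nodes:
        i = index[v]
        rows.append(i)
        cols.append(i)
        for u in network.neighbors(v):
            if u == v:
                continue
            rows.append(i)
            cols.append(index[u])
    closed_adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )

    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=np.ones(n),
        constraints=LinearConstraint(closed_adj, lb=1, ub=np.inf),
        integrality=np.ones(n),
        bounds=Bounds(0, 1),
        options=options,
    )
    if res.x is None:
        raise RuntimeError(f"MILP solver returned no solution: {res.message}")
    members = {nodes[i] for i in range(n) if res.x[i] > 0.5}
    optimal = bool(res.status == 0)
    if not verify_dominating(network, members):
        raise RuntimeError("solver returned a non-dominating set")
    return MDSResult(members, len(members), "ilp", optimal)


def solve_mds_exhaustive(network: PPINetwork, max_nodes: int = 20) -> MDSResult:
    """Smallest dominating set by subset enumeration in increasing size.

    Ties at the minimum size resolve to the lexicographically first
    member set.  Refuses graphs larger than ``max_nodes``.
    """
    nodes = sorted(network.nodes)
    if len(nodes) > max_nodes:
        raise ValueError(
            f"exhaustive search limited to {max_nodes} nodes "
            f"(got {len(nodes)})"
        )
    if not nodes:
        return MDSResult(set(), 0, "exhaustive", True)
    closed = {
        v: (network.neighbors(v) | {v}) for v in nodes
    }
    universe = set(nodes)
    for size in range(1, len(nodes) + 1):
        for combo in combinations(nodes, size):
            covered: set[str] = set()
            for v in combo:
                covered |= closed[v]
            if covered == universe:
                return MDSResult(set(combo), size, "exhaustive", True)
    raise AssertionError("unreachable: full node set always dominates")


def greedy_mds(network: PPINetwork) -> MDSResult:
    """Greedy cover: repeatedly take the node dominating the most
    currently-undominated nodes (ties: higher degree, then lexicographic)."""
    nodes = sorted(network.nodes)
    closed = {v: (network.neighbors(v) | {v}) for v in nodes}
    degree = {v: network.graph.degree(v) for v in nodes}
    undominated = set(nodes)
    members: set[str] = set()
    while undominated:
        best = min(
            nodes,
            key=lambda v: (-len(closed[v] & undominated), -degree[v], v),
        )
        members.add(best)
        undominated -= closed[best]
    if not verify_dominating(network, members):
        raise AssertionError("greedy produced a non-dominating set")
    return MDSResult(members, len(members), "greedy", False)
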