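"""Network quality assessment against degree-preserving random networks.

Two orthogonal signals are checked: interacting proteins should have
similar GO annotations (graph-based Wang semantic similarity combined
with best-match averaging) and correlated transcription profiles
(Pearson correlation over RPKM time courses).  Each edge-level
distribution is compared with the pooled distribution from degree-
preserving rewirings of the same network using the Wilcoxon rank-sum
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .io_formats import AnnotationSet, ExpressionMatrix, GoDag
from .network import PPINetwork, rewire_preserving_degrees

WANG_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class SimilarityDistribution:
    values: list[float]
    source: str  # "ppi" | "random"
    n_random_networks: int = 0
    n_skipped_pairs: int = 0


@dataclass
class TestReport:
    statistic: float
    p_value: float
    alternative: str
    n_x: int
    n_y: int
    method: str = ""


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Midrank sum of the x sample within the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    return float(np.sum(ranks[: len(x)]))


def wilcoxon_rank_sum(
    x, y, alternative: str = "two-sided"
) -> TestReport:
    """Wilcoxon rank-sum test on two independent samples.

    The statistic is the rank sum of ``x`` (midranks for ties).  When the
    pooled size is <= 12 and there are no ties the one/two-sided P is
    exact, by enumerating all rank assignments; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    w = _rank_sum_statistic(x, y)
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size

    if n_x + n_y <= 12 and not has_ties:
        p = _exact_rank_sum_p(w, n_x, n_y, alternative)
        method = "exact"
    else:
        p = _normal_rank_sum_p(w, x, y, alternative)
        method = "normal-approximation"
    return TestReport(
        statistic=w,
        p_value=p,
        alternative=alternative,
        n_x=int(n_x),
        n_y=int(n_y),
        method=method,
    )


def _exact_rank_sum_p(w: float, n_x: int, n_y: int, alternative: str) -> float:
    n = n_x + n_y
    sums = [sum(c) for c in combinations(range(1, n + 1), n_x)]
    total = len(sums)
    ge = sum(1 for s in sums if s >= w - 1e-9) / total
    le = sum(1 for s in sums if s <= w + 1e-9) / total
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def _normal_rank_sum_p(
    w: float, x: np.ndarray, y: np.ndarray, alternative: str
) -> float:
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    mu = n_x * (n + 1) / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        z = (w - mu - 0.5) / sd
        return float(stats.norm.sf(z))
    if alternative == "less":
        z = (w - mu + 0.5) / sd
        return float(stats.norm.cdf(z))
    z = (abs(w - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Wang semantic similarity
# ---------------------------------------------------------------------------


class SemanticSimilarity:
    """Wang graph-based GO term similarity with per-term caching.

    The S-value of an ancestor t in the annotation graph of a term A is
    the maximal product of edge weights (is_a 0.8, part_of 0.6) over
    paths from A up to t, with S_A(A) = 1.  The similarity of A and B is
    the sum of (S_A(t) + S_B(t)) over shared ancestors, normalized by
    SV(A) + SV(B).
    """

    def __init__(self, dag: GoDag) -> None:
        self.dag = dag
        self._svalues: dict[str, dict[str, float]] = {}
        self._pair_cache: dict[tuple[str, str], float] = {}

    def s_values(self, term: str) -> dict[str, float]:
        cached = self._svalues.get(term)
        if cached is not None:
            return cached
        if term not in self.dag.terms:
            raise KeyError(f"term {term} not in DAG")
        s: dict[str, float] = {term: 1.0}
        # best-first relaxation upward; weights < 1 so a simple stack
        # with max-update converges
        stack = [term]
        while stack:
            node = stack.pop()
            base = s[node]
            for parent, rel in self.dag.parents(node):
                cand = base * WANG_EDGE_WEIGHTS[rel]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    stack.append(parent)
        self._svalues[term] = s
        return s

    def term_similarity(self, term_a: str, term_b: str) -> float:
        if term_a == term_b:
            return 1.0
        ns_a = self.dag.namespace.get(term_a)
        ns_b = self.dag.namespace.get(term_b)
        if ns_a != ns_b:
            raise ValueError(
                f"cross-namespace similarity undefined: {term_a} ({ns_a}) "
                f"vs {term_b} ({ns_b})"
            )
        key = (term_a, term_b) if term_a < term_b else (term_b, term_a)
        cached = self._pair_cache.get(key)
        if cached is not None:
            return cached
        sa = self.s_values(term_a)
        sb = self.s_values(term_b)
        common = sa.keys() & sb.keys()
        if not common:
            sim = 0.0
        else:
            sim = sum(sa[t] + sb[t] for t in common) / (
                sum(sa.values()) + sum(sb.values())
            )
        self._pair_cache[key] = sim
        return sim

    def protein_similarity(
        self, terms_a: set[str], terms_b: set[str]
    ) -> float | None:
        """Best-match-average similarity of two annotated proteins.

        Per namespace in which both proteins have terms, BMA = the mean
        of per-row maxima and per-column maxima of the term-similarity
        matrix, averaged; the protein score averages over those
        namespaces.  None when no namespace is shared.
        """
        by_ns_a: dict[str, list[str]] = {}
        for t in terms_a:
            ns = self.dag.namespace.get(t)
            if ns is not None:
                by_ns_a.setdefault(ns, []).append(t)
        by_ns_b: dict[str, list[str]] = {}
        for t in terms_b:
            ns = self.dag.namespace.get(t)
            if ns is not None:
                by_ns_b.setdefault(ns, []).append(t)

        ns_scores = []
        for ns in sorted(by_ns_a.keys() & by_ns_b.keys()):
            ta = sorted(by_ns_a[ns])
            tb = sorted(by_ns_b[ns])
            matrix = np.array(
                [[self.term_similarity(a, b) for b in tb] for a in ta]
            )
            bma = 0.5 * (
                float(np.mean(matrix.max(axis=1)))
                + float(np.mean(matrix.max(axis=0)))
            )
            ns_scores.append(bma)
        if not ns_scores:
            return None
        return float(np.mean(ns_scores))


def go_term_similarity(term_a: str, term_b: str, dag: GoDag) -> float:
    return SemanticSimilarity(dag).term_similarity(term_a, term_b)


def protein_functional_similarity(
    protein_a: str,
    protein_b: str,
    annotations: AnnotationSet,
    dag: GoDag,
    calculator: SemanticSimilarity | None = None,
) -> float | None:
    calc = calculator or SemanticSimilarity(dag)
    terms_a = annotations.go.get(protein_a, set())
    terms_b = annotations.go.get(protein_b, set())
    if not terms_a or not terms_b:
        return None
    return calc.protein_similarity(terms_a, terms_b)


# ---------------------------------------------------------------------------
# Edge-level distributions and the random-network comparison
# ---------------------------------------------------------------------------


def network_similarity_distribution(
    network: PPINetwork,
    annotations: AnnotationSet,
    dag: GoDag,
    calculator: SemanticSimilarity | None = None,
    source: str = "ppi",
) -> SimilarityDistribution:
    """GO functional similarity over all edges with computable pairs."""
    calc = calculator or SemanticSimilarity(dag)
    values: list[float] = []
    skipped = 0
    for a, b in sorted(network.edges):
        if a == b:
            continue
        sim = protein_functional_similarity(a, b, annotations, dag, calc)
        if sim is None:
            skipped += 1
        else:
            values.append(sim)
    return SimilarityDistribution(
        values=values, source=source, n_skipped_pairs=skipped
    )


def _pooled_random_values(
    network: PPINetwork,
    edge_value,
    n_random: int,
    seed: int,
) -> list[float]:
    values: list[float] = []
    for rep in range(n_random):
        rewired = rewire_preserving_degrees(network, seed=seed + rep)
        for a, b in sorted(rewired.edges):
            v = edge_value(a, b)
            if v is not None:
                values.append(v)
    return values


def compare_with_random(
    network: PPINetwork,
    annotations: AnnotationSet,
    dag: GoDag,
    n_random: int = 100,
    seed: int = 0,
) -> TestReport:
    """Wilcoxon comparison of edge GO similarity vs rewired-network pool.

    Alternative "greater": a well-predicted network joins functionally
    similar proteins more often than degree-matched chance.
    """
    calc = SemanticSimilarity(dag)
    ppi = network_similarity_distribution(network, annotations, dag, calc)
    if not ppi.values:
        raise ValueError("no edge pair has computable GO similarity")

    def edge_sim(a: str, b: str) -> float | None:
        return protein_functional_similarity(a, b, annotations, dag, calc)

    random_values = _pooled_random_values(network, edge_sim, n_random, seed)
    if not random_values:
        raise ValueError("no computable pairs in the random networks")
    return wilcoxon_rank_sum(ppi.values, random_values, alternative="greater")


def edge_expression_pcc(
    a: str, b: str, expression: ExpressionMatrix
) -> float | None:
    va = expression.rpkm.get(a)
    vb = expression.rpkm.get(b)
    if va is None or vb is None:
        return None
    if np.std(va) == 0 or np.std(vb) == 0:
        return None
    return float(np.corrcoef(va, vb)[0, 1])


def transcription_pcc_validation(
    network: PPINetwork,
    expression: ExpressionMatrix,
    n_random: int = 100,
    seed: int = 0,
) -> TestReport:
    """Compare edge-wise transcription PCC against rewired networks."""
    if len(expression.time_labels) < 3:
        raise ValueError(
            "need >=3 time points for a meaningful correlation"
        )
    ppi_values = [
        v
        for a, b in sorted(network.edges)
        if a != b
        for v in [edge_expression_pcc(a, b, expression)]
        if v is not None
    ]
    if not ppi_values:
        raise ValueError("no edge has computable expression correlation")
    random_values = _pooled_random_values(
        network,
        lambda a, b: edge_expression_pcc(a, b, expression),
        n_random,
        seed,
    )
    return wilcoxon_rank_sum(ppi_values, random_values, alternative="greater")
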