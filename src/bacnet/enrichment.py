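"""Functional-category statistics over the PPI network.

Covers the COG-pair interaction heat map (Z-scores under a binomial
null), Fisher's exact enrichment of a node set, the functional-category
entropy of protein complexes, and module-assisted annotation of
uncharacterized proteins.

The heat-map null model: among the n COG-annotated proteins of the
network there are T = n(n-1)/2 possible pairs; a random network placing
N interactions among them gives the count of class-(i, j) interactions a
Binomial(N, P_ij) distribution with

    P_ij = f_i * f_j / T          (i != j)
    P_ii = f_i (f_i - 1) / 2 / T

where f_i is the number of proteins carrying category i.  The Z-score of
the observed count A_ij is (A_ij - N P_ij) / sqrt(N P_ij (1 - P_ij)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationSet, canonical_pair
from .network import PPINetwork

UNCHARACTERIZED_CATEGORIES = {"S", "R"}
"""COG letters treated as 'function unknown / general prediction only'."""


@dataclass
class CogHeatmap:
    categories: list[str]
    counts: np.ndarray      # A_ij, symmetric
    expected: np.ndarray    # N * P_ij
    z: np.ndarray           # NaN where P_ij in {0, 1}
    n: int                  # annotated proteins in the network
    N: int                  # interactions among annotated proteins

    def zscore(self, cat_i: str, cat_j: str) -> float:
        i = self.categories.index(cat_i)
        j = self.categories.index(cat_j)
        return float(self.z[i, j])


def cog_heatmap(network: PPINetwork, annotations: AnnotationSet) -> CogHeatmap:
    """COG-pair interaction counts and Z-scores under the binomial null.

    Only proteins carrying at least one COG category participate.  A
    multi-label protein counts once in f_i for each of its categories; an
    edge contributes one count to every distinct unordered category
    combination of its two endpoints.
    """
    annotated = sorted(
        v for v in network.nodes if annotations.cog.get(v)
    )
    n = len(annotated)
    if n < 2:
        raise ValueError("need >=2 COG-annotated proteins in the network")
    annotated_set = set(annotated)

    f: dict[str, int] = {}
    for v in annotated:
        for cat in set(annotations.cog[v]):
            f[cat] = f.get(cat, 0) + 1
    categories = sorted(f)
    idx = {c: i for i, c in enumerate(categories)}
    k = len(categories)

    counts = np.zeros((k, k))
    N = 0
    for a, b in network.edges:
        if a == b or a not in annotated_set or b not in annotated_set:
            continue
        N += 1
        combos = {
            canonical_pair(ci, cj)
            for ci in set(annotations.cog[a])
            for cj in set(annotations.cog[b])
        }
        for ci, cj in combos:
            i, j = idx[ci], idx[cj]
            counts[i, j] += 1
            if i != j:
                counts[j, i] += 1

    T = n * (n - 1) / 2.0
    fvec = np.array([f[c] for c in categories], dtype=float)
    P = np.outer(fvec, fvec) / T
    np.fill_diagonal(P, fvec * (fvec - 1) / 2.0 / T)
    expected = N * P

    with np.errstate(divide="ignore", invalid="ignore"):
        var = N * P * (1.0 - P)
        z = (counts - expected) / np.sqrt(var)
    z[(P <= 0) | (P >= 1)] = np.nan

    return CogHeatmap(
        categories=categories, counts=counts, expected=expected, z=z, n=n, N=N
    )


@dataclass
class EnrichmentResult:
    category: str
    in_set: int
    set_size: int
    in_background: int
    background_size: int
    p_value: float
    p_adjusted: float
    enriched: bool

    def __post_init__(self) -> None:
        if self.in_set > self.in_background:
            raise ValueError("in_set cannot exceed in_background")


def fisher_enrichment(
    member_set: set[str],
    background: set[str],
    annotations: AnnotationSet,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided (enrichment) Fisher's exact test per COG category.

    The 2x2 table per category: members in/out of the category vs
    non-member background proteins in/out of it.  Raw P-values drive the
    ``enriched`` flag at ``alpha``; Benjamini–Hochberg adjusted values are
    reported alongside.
    """
    if not member_set:
        raise ValueError("member_set is empty")
    if not member_set <= background:
        raise ValueError("member_set must be a subset of background")

    categories = sorted(
        {c for p in background for c in annotations.cog.get(p, [])}
    )
    results: list[EnrichmentResult] = []
    raw: list[float] = []
    m, bg = len(member_set), len(background)
    for cat in categories:
        with_cat = {p for p in background if cat in annotations.cog.get(p, [])}
        a = len(member_set & with_cat)
        table = [[a, m - a], [len(with_cat) - a, bg - m - (len(with_cat) - a)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        raw.append(float(p))
        results.append(
            EnrichmentResult(
                category=cat,
                in_set=a,
                set_size=m,
                in_background=len(with_cat),
                background_size=bg,
                p_value=float(p),
                p_adjusted=float("nan"),
                enriched=bool(p < alpha),
            )
        )
    if raw:
        adjusted = multipletests(raw, method="fdr_bh")[1]
        for res, padj in zip(results, adjusted):
            res.p_adjusted = float(padj)
    return results


@dataclass
class ComplexEntropy:
    """Shannon entropy (bits) of a complex's category composition.

    Each member contributes its primary (first-listed) COG category, or
    "unknown" when unannotated, so counts sum to the member count.
    """

    complex_id: str
    n_members: int
    category_counts: dict[str, int] = field(default_factory=dict)
    entropy: float = 0.0
    all_unknown: bool = False


def functional_entropy(
    members: list[str],
    annotations: AnnotationSet,
    complex_id: str = "",
) -> ComplexEntropy:
    if not members:
        raise ValueError("complex has no members")
    counts: dict[str, int] = {}
    for member in members:
        cat = annotations.primary_cog(member)
        counts[cat] = counts.get(cat, 0) + 1
    n = len(members)
    entropy = -sum(
        (c / n) * math.log2(c / n) for c in counts.values() if c > 0
    )
    return ComplexEntropy(
        complex_id=complex_id,
        n_members=n,
        category_counts=counts,
        entropy=entropy,
        all_unknown=(set(counts) == {"unknown"}),
    )


def is_uncharacterized(protein: str, annotations: AnnotationSet) -> bool:
    cats = set(annotations.cog.get(protein, []))
    return not cats or cats <= UNCHARACTERIZED_CATEGORIES


def annotate_uncharacterized(
    complexes: list[list[str]],
    annotations: AnnotationSet,
    background: set[str],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Assign enriched complex categories to uncharacterized members.

    For each complex, categories significantly enriched (raw Fisher P <
    alpha, informative categories only) are propagated to members whose
    COG annotation is empty or limited to the uninformative letters S/R.
    A protein reached by several complexes keeps the assignment with the
    smallest enrichment P.
    """
    best: dict[str, tuple[float, str]] = {}
    for members in complexes:
        member_set = set(members) & background
        if not member_set:
            continue
        enriched = [
            r
            for r in fisher_enrichment(member_set, background, annotations, alpha)
            if r.enriched and r.category not in UNCHARACTERIZED_CATEGORIES
        ]
        if not enriched:
            continue
        top = min(enriched, key=lambda r: (r.p_value, r.category))
        for member in members:
            if not is_uncharacterized(member, annotations):
                continue
            incumbent = best.get(member)
            if incumbent is None or (top.p_value, top.category) < incumbent:
                best[member] = (top.p_value, top.category)
    return {protein: cat for protein, (_, cat) in best.items()}
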