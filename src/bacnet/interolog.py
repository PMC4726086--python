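"""Homology-based (interolog) interaction transfer.

A pair of target proteins is predicted to interact when their orthologs in
a reference organism have an experimentally determined interaction.
Candidate orthologs come from similarity-search hits filtered on E-value,
percent identity and alignment coverage; when a target protein matches
several proteins in one reference organism, only the highest-scoring hit is
kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import EdgeRecord, HomologyHit, canonical_pair, merge_edge_records


@dataclass(frozen=True)
class InterologThresholds:
    """Filter thresholds for ortholog candidate hits.

    Defaults are the conventional stringent choice for cross-species
    interaction transfer: E-value <= 1e-5, identity >= 30%, coverage >= 60%.
    ``coverage_mode`` controls whether coverage must hold for both sequences
    (``min``, default — the stricter symmetric reading) or only the query
    (``query``).
    """

    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_coverage: float = 60.0
    coverage_mode: str = "min"

    def __post_init__(self) -> None:
        if self.max_evalue <= 0 or self.min_identity <= 0 or self.min_coverage <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_identity > 100 or self.min_coverage > 100:
            raise ValueError("identity/coverage thresholds are percentages <= 100")
        if self.coverage_mode not in ("min", "query"):
            raise ValueError("coverage_mode must be 'min' or 'query'")


@dataclass
class OrthologMap:
    """Best ortholog per (target protein, reference organism)."""

    pairs: dict[tuple[str, str], str] = field(default_factory=dict)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def organisms(self) -> set[str]:
        return {org for (_, org) in self.pairs}

    def by_organism(self, organism: str) -> dict[str, str]:
        """target protein -> subject protein for one reference organism."""
        return {
            target: subject
            for (target, org), subject in self.pairs.items()
            if org == organism
        }


def hit_coverage(hit: HomologyHit, mode: str = "min") -> float:
    qcov = hit.query_coverage
    if mode == "query":
        return qcov
    return min(qcov, hit.subject_coverage)


def filter_homology_hits(
    hits: Iterable[HomologyHit],
    thresholds: InterologThresholds = InterologThresholds(),
) -> list[HomologyHit]:
    """Keep hits passing all three thresholds, preserving input order."""
    kept = []
    for hit in hits:
        if hit.evalue > thresholds.max_evalue:
            continue
        if hit.percent_identity < thresholds.min_identity:
            continue
        if hit_coverage(hit, thresholds.coverage_mode) < thresholds.min_coverage:
            continue
        kept.append(hit)
    return kept


def best_hit_per_organism(hits: Iterable[HomologyHit]) -> OrthologMap:
    """Reduce filtered hits to the single best subject per (query, organism).

    Best = maximal bit score; ties broken by smaller E-value, then by
    lexicographically smaller subject id, so the result is deterministic.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.subject_organism)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = hit
            continue
        challenger = (-hit.bit_score, hit.evalue, hit.subject_id)
        holder = (-incumbent.bit_score, incumbent.evalue, incumbent.subject_id)
        if challenger < holder:
            best[key] = hit
    omap = OrthologMap()
    for key, hit in best.items():
        omap.pairs[key] = hit.subject_id
        omap.scores[key] = hit.bit_score
    return omap


def transfer_interactions(
    ortholog_map: OrthologMap,
    reference_ppis: Sequence[tuple[str, str, str]] | Sequence[EdgeRecord],
) -> list[EdgeRecord]:
    """Transfer reference interactions onto the target proteome.

    ``reference_ppis`` rows are ``(protein_a, protein_b, organism)`` tuples
    or EdgeRecords whose first source names the organism.  A target edge
    (A, B) is emitted whenever A and B map to the two endpoints of a
    reference edge within the same organism.  Homomeric transfers (A == B)
    are produced and carry the ``self_loop`` evidence tag.
    """
    rows: list[tuple[str, str, str]] = []
    for item in reference_ppis:
        if isinstance(item, EdgeRecord):
            org = item.sources[0] if item.sources else "unknown"
            rows.append((item.protein_a, item.protein_b, org))
        else:
            rows.append(tuple(item))  # type: ignore[arg-type]

    # organism -> subject -> list of target proteins mapping to it
    reverse: dict[str, dict[str, list[str]]] = {}
    for (target, org), subject in ortholog_map.pairs.items():
        reverse.setdefault(org, {}).setdefault(subject, []).append(target)

    predictions: list[EdgeRecord] = []
    for sub_a, sub_b, org in rows:
        targets = reverse.get(org)
        if not targets:
            continue
        for ta in targets.get(sub_a, []):
            for tb in targets.get(sub_b, []):
                a, b = canonical_pair(ta, tb)
                evidence = {"interolog"}
                if a == b:
                    evidence.add("self_loop")
                predictions.append(EdgeRecord(a, b, evidence, [org]))
    return merge_edge_records(predictions)
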