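"""Domain-pair-based interaction prediction.

Two proteins are predicted to interact when they carry a pair of domains
with experimentally or structurally determined interaction (as catalogued
by resources such as iPfam and 3did).  Domain assignments come from
profile-HMM search hits filtered on full-sequence E-value and bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import DomainHit, EdgeRecord, canonical_pair, merge_edge_records


@dataclass
class DomainAssignment:
    """Protein -> set of domain accessions (post-filtering)."""

    domains: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class DdiSet:
    """Canonical unordered domain-accession pairs; self-pairs allowed."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DdiSet":
        return cls({canonical_pair(a, b) for a, b in pairs})

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def partners(self) -> dict[str, set[str]]:
        """domain -> set of domains it interacts with (incl. itself)."""
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
            out.setdefault(b, set()).add(a)
        return out


def read_ddi_table(path) -> DdiSet:
    """Read a two-column TSV of interacting domain-accession pairs."""
    from .io_formats import FormatError, _data_lines, strip_accession_version

    pairs: set[tuple[str, str]] = set()
    for lineno, line in _data_lines(path):
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 2:
            raise FormatError(f"{path}:{lineno}: DDI rows need 2 columns")
        a = strip_accession_version(cols[0])
        b = strip_accession_version(cols[1])
        pairs.add(canonical_pair(a, b))
    return DdiSet(pairs)


def write_ddi_table(ddis: DdiSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#domain_a\tdomain_b\n")
        for a, b in sorted(ddis.pairs):
            fh.write(f"{a}\t{b}\n")


def assign_domains(
    hits: Iterable[DomainHit],
    max_evalue: float = 1e-5,
    max_bias: float = 1.0,
) -> DomainAssignment:
    """Filter hits (E-value and bias caps) and collapse to per-protein sets."""
    assignment = DomainAssignment()
    for hit in hits:
        if hit.evalue > max_evalue or hit.bias > max_bias:
            continue
        assignment.domains.setdefault(hit.protein_id, set()).add(
            hit.domain_accession
        )
    return assignment


def predict_from_ddi(assignment: DomainAssignment, ddis: DdiSet) -> list[EdgeRecord]:
    """Emit every protein pair carrying at least one interacting domain pair.

    A single supporting domain pair suffices; all supporting pairs are
    recorded as sources ("m|n").  A protein whose own domain set contains
    an interacting pair (including a self-interacting domain) yields a
    flagged self-loop.
    """
    # domain -> proteins carrying it
    carriers: dict[str, list[str]] = {}
    for protein, domains in assignment.domains.items():
        for d in domains:
            carriers.setdefault(d, []).append(protein)

    support: dict[tuple[str, str], set[str]] = {}
    for dm, dn in ddis.pairs:
        for x in carriers.get(dm, []):
            for y in carriers.get(dn, []):
                pair = canonical_pair(x, y)
                support.setdefault(pair, set()).add(f"{dm}|{dn}")

    records = []
    for (a, b), ddi_sources in sorted(support.items()):
        evidence = {"ddi"}
        if a == b:
            evidence.add("self_loop")
        records.append(EdgeRecord(a, b, evidence, sorted(ddi_sources)))
    return merge_edge_records(records)
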