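"""Readers and writers for the tabular and OBO formats the pipeline consumes.

All readers are strict: malformed rows raise :class:`FormatError` with the
offending line number rather than being silently coerced or dropped.
Identifiers are opaque, case-sensitive strings; the comment character is
``#`` and files are assumed UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

COG_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ") - {"X"}
"""Single-letter COG functional categories (25 letters; X is unused)."""

GO_NAMESPACES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyHit:
    """One row of a protein similarity-search hit table.

    ``percent_identity`` is on the 0–100 scale; coverage of the query and
    subject is derived from ``alignment_length`` and the two sequence
    lengths.
    """

    query_id: str
    subject_id: str
    subject_organism: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bit_score: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise FormatError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length <= 0:
            raise FormatError("alignment_length must be positive")
        if self.evalue < 0:
            raise FormatError("evalue must be non-negative")

    @property
    def query_coverage(self) -> float:
        """Alignment length as a percentage of the query length."""
        if self.query_length <= 0:
            raise FormatError(f"query_length must be positive for {self.query_id}")
        return 100.0 * self.alignment_length / self.query_length

    @property
    def subject_coverage(self) -> float:
        """Alignment length as a percentage of the subject length."""
        if self.subject_length <= 0:
            raise FormatError(f"subject_length must be positive for {self.subject_id}")
        return 100.0 * self.alignment_length / self.subject_length


@dataclass(frozen=True)
class DomainHit:
    """One protein→domain assignment from a profile-HMM search table."""

    protein_id: str
    domain_accession: str
    evalue: float
    bias: float
    score: float

    def __post_init__(self) -> None:
        if not self.domain_accession:
            raise FormatError("domain_accession must be non-empty")
        if self.evalue < 0:
            raise FormatError("evalue must be non-negative")
        if self.bias < 0:
            raise FormatError("bias must be non-negative")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair (a, b) in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeRecord:
    """An unordered protein pair with evidence provenance.

    Stored canonically: ``protein_a <= protein_b`` lexicographically.
    ``evidence`` holds tags such as ``interolog`` / ``ddi``; ``sources``
    lists supporting reference organisms or domain pairs.
    """

    protein_a: str
    protein_b: str
    evidence: set[str] = field(default_factory=set)
    sources: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise FormatError("edge endpoints must be non-empty")
        a, b = canonical_pair(self.protein_a, self.protein_b)
        self.protein_a, self.protein_b = a, b

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def is_self_loop(self) -> bool:
        return self.protein_a == self.protein_b


@dataclass
class AnnotationSet:
    """Protein → COG categories (ordered, multi-label) and GO terms."""

    cog: dict[str, list[str]] = field(default_factory=dict)
    go: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, cats in self.cog.items():
            bad = [c for c in cats if c not in COG_ALPHABET]
            if bad:
                raise FormatError(f"unknown COG letter(s) {bad} for {pid}")

    def primary_cog(self, protein: str) -> str:
        """First-listed COG category of a protein, or 'unknown'."""
        cats = self.cog.get(protein, [])
        return cats[0] if cats else "unknown"

    def categories_present(self) -> list[str]:
        present: set[str] = set()
        for cats in self.cog.values():
            present.update(cats)
        return sorted(present)


@dataclass
class GoDag:
    """A directed acyclic graph of GO terms (is_a / part_of subset).

    ``edges`` maps each child term to a list of ``(parent, relation)``
    tuples; relations are ``is_a`` or ``part_of``.
    """

    terms: set[str]
    edges: dict[str, list[tuple[str, str]]]
    namespace: dict[str, str]

    def parents(self, term: str) -> list[tuple[str, str]]:
        return self.edges.get(term, [])

    def validate(self) -> None:
        for child, parents in self.edges.items():
            if child not in self.terms:
                raise FormatError(f"edge source {child} is not a defined term")
            for parent, rel in parents:
                if parent not in self.terms:
                    raise FormatError(
                        f"term {child} references undefined parent {parent}"
                    )
                if rel not in ("is_a", "part_of"):
                    raise FormatError(f"unknown relation {rel!r} on {child}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative three-colour DFS over child->parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.terms}
        for start in self.terms:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            colour[start] = GREY
            while stack:
                node, idx = stack[-1]
                parents = self.edges.get(node, [])
                if idx < len(parents):
                    stack[-1] = (node, idx + 1)
                    nxt = parents[idx][0]
                    if colour[nxt] == GREY:
                        raise FormatError(f"cycle detected through term {nxt}")
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    colour[node] = BLACK
                    stack.pop()


@dataclass
class ExpressionMatrix:
    """Protein → RPKM vector, one entry per time point."""

    rpkm: dict[str, np.ndarray]
    time_labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.time_labels)
        for pid, vec in self.rpkm.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise FormatError(
                    f"expression vector for {pid} has length {vec.shape}, "
                    f"expected {n}"
                )
            if np.any(vec < 0):
                raise FormatError(f"negative RPKM for {pid}")
            self.rpkm[pid] = vec

    def time_index(self, label: str) -> int:
        try:
            return self.time_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown time label {label!r}") from None

    def value(self, protein: str, label: str) -> float | None:
        vec = self.rpkm.get(protein)
        if vec is None:
            return None
        return float(vec[self.time_index(label)])


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _parse_float(text: str, path, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-numeric {what} field {text!r}"
        ) from None


def _parse_int(text: str, path, lineno: int, what: str) -> int:
    try:
        return int(float(text))
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer {what} field {text!r}"
        ) from None


def resolve_organism(subject_id: str, organism_map: Mapping[str, str]) -> str:
    """Resolve a subject identifier to an organism by longest prefix match."""
    best = ""
    organism = "unknown"
    for prefix, org in organism_map.items():
        if subject_id.startswith(prefix) and len(prefix) > len(best):
            best, organism = prefix, org
    return organism


def read_homology_table(path, organism_map: Mapping[str, str]) -> list[HomologyHit]:
    """Read a 14-column similarity-search hit table.

    Columns are the standard 12-column tabular layout (qseqid, sseqid,
    pident, length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore) with query and subject sequence lengths appended as columns
    13–14; the lengths are required to compute alignment coverage.
    """
    hits: list[HomologyHit] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 14:
            raise FormatError(
                f"{path}:{lineno}: expected 14 tab-separated columns, "
                f"got {len(cols)}"
            )
        try:
            hit = HomologyHit(
                query_id=cols[0],
                subject_id=cols[1],
                subject_organism=resolve_organism(cols[1], organism_map),
                percent_identity=_parse_float(cols[2], path, lineno, "pident"),
                alignment_length=_parse_int(cols[3], path, lineno, "length"),
                evalue=_parse_float(cols[10], path, lineno, "evalue"),
                bit_score=_parse_float(cols[11], path, lineno, "bitscore"),
                query_length=_parse_int(cols[12], path, lineno, "qlen"),
                subject_length=_parse_int(cols[13], path, lineno, "slen"),
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        hits.append(hit)
    return hits


def strip_accession_version(accession: str) -> str:
    """Normalize a domain accession by removing a trailing '.N' version."""
    stem, dot, suffix = accession.partition(".")
    if dot and suffix.isdigit():
        return stem
    return accession


def read_domain_table(path) -> list[DomainHit]:
    """Read a protein→domain hit table.

    The native layout is a reduced 5-column table: protein_id,
    domain_accession, full-sequence E-value, bias, score (tab- or
    whitespace-separated).  A full-width 23-column per-domain tabular file
    is also accepted; in that layout the columns used are target name (1),
    accession (2 — falling back to the target name when '-'), full-sequence
    E-value (7), score (8) and bias (9).
    """
    hits: list[DomainHit] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) >= 23:
            protein = cols[3]
            accession = cols[1] if cols[1] != "-" else cols[0]
            ev, score, bias = cols[6], cols[7], cols[8]
        elif len(cols) == 5:
            protein, accession, ev, bias, score = cols
        else:
            raise FormatError(
                f"{path}:{lineno}: expected 5 (reduced) or >=23 (full) "
                f"columns, got {len(cols)}"
            )
        try:
            hit = DomainHit(
                protein_id=protein,
                domain_accession=strip_accession_version(accession),
                evalue=_parse_float(ev, path, lineno, "evalue"),
                bias=_parse_float(bias, path, lineno, "bias"),
                score=_parse_float(score, path, lineno, "score"),
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        hits.append(hit)
    return hits


def merge_edge_records(records: Iterable[EdgeRecord]) -> list[EdgeRecord]:
    """Merge duplicate unordered pairs, taking the union of evidence/sources."""
    merged: dict[tuple[str, str], EdgeRecord] = {}
    for rec in records:
        key = rec.pair
        if key in merged:
            existing = merged[key]
            existing.evidence |= rec.evidence
            for src in rec.sources:
                if src not in existing.sources:
                    existing.sources.append(src)
        else:
            merged[key] = EdgeRecord(
                rec.protein_a, rec.protein_b, set(rec.evidence), list(rec.sources)
            )
    return [merged[k] for k in sorted(merged)]


def read_edge_list(path) -> list[EdgeRecord]:
    """Read a TSV edge list: protein_a, protein_b[, evidence[, sources]].

    Evidence tags are comma-joined in column 3; sources comma-joined in
    column 4.  Duplicate unordered pairs are merged with evidence union and
    the result is canonically ordered.
    """
    records: list[EdgeRecord] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise FormatError(
                f"{path}:{lineno}: edge rows need at least 2 columns"
            )
        evidence = (
            {t for t in cols[2].split(",") if t} if len(cols) >= 3 else set()
        )
        sources = (
            [s for s in cols[3].split(",") if s] if len(cols) >= 4 else []
        )
        try:
            records.append(EdgeRecord(cols[0], cols[1], evidence, sources))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    return merge_edge_records(records)


def write_edge_list(records: Sequence[EdgeRecord], path) -> None:
    """Write edge records as a 4-column TSV (inverse of :func:`read_edge_list`)."""
    records = merge_edge_records(records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\tevidence\tsources\n")
        for rec in records:
            fh.write(
                f"{rec.protein_a}\t{rec.protein_b}\t"
                f"{','.join(sorted(rec.evidence))}\t{','.join(rec.sources)}\n"
            )


# ---------------------------------------------------------------------------
# OBO subset reader
# ---------------------------------------------------------------------------


def read_obo_subset(path) -> GoDag:
    """Parse an OBO file restricted to [Term] stanzas.

    Handles ``id``, ``namespace``, ``is_a`` and ``relationship: part_of``
    tags; obsolete terms are skipped.  The resulting DAG is validated for
    acyclicity and dangling parents.
    """
    terms: set[str] = set()
    edges: dict[str, list[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}

    current: dict | None = None
    in_term = False

    def flush() -> None:
        nonlocal current
        if current is None or current.get("obsolete"):
            current = None
            return
        tid = current.get("id")
        if tid is None:
            raise FormatError(f"{path}: [Term] stanza without an id")
        terms.add(tid)
        if "namespace" in current:
            namespace[tid] = current["namespace"]
        if current["parents"]:
            edges[tid] = current["parents"]
        current = None

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                current = {"parents": []} if in_term else None
                continue
            if current is None or not line or line.startswith("!"):
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            key = key.strip()
            if key == "id":
                current["id"] = value
            elif key == "namespace":
                current["namespace"] = GO_NAMESPACES.get(value, value)
            elif key == "is_a":
                current["parents"].append((value, "is_a"))
            elif key == "relationship":
                rel, _, target = value.partition(" ")
                if rel == "part_of":
                    current["parents"].append((target.strip(), "part_of"))
            elif key == "is_obsolete" and value.lower() == "true":
                current["obsolete"] = True
    flush()

    dag = GoDag(terms=terms, edges=edges, namespace=namespace)
    dag.validate()
    return dag


def write_obo_subset(dag: GoDag, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        inverse_ns = {v: k for k, v in GO_NAMESPACES.items()}
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            ns = dag.namespace.get(term)
            if ns:
                fh.write(f"namespace: {inverse_ns.get(ns, ns)}\n")
            for parent, rel in dag.parents(term):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


# ---------------------------------------------------------------------------
# Annotation and expression tables
# ---------------------------------------------------------------------------


def read_annotation_table(path, dag: GoDag | None = None) -> AnnotationSet:
    """Read a protein annotation TSV: protein_id, COG letters, GO ids.

    COG letters are comma-joined in column 2 (may be empty); GO term ids
    semicolon-joined in column 3 (optional column).  When a DAG is supplied
    every GO term must exist in it.
    """
    cog: dict[str, list[str]] = {}
    go: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise FormatError(
                f"{path}:{lineno}: annotation rows need >=2 columns"
            )
        pid = cols[0]
        letters = [c for c in cols[1].split(",") if c]
        if letters:
            cog[pid] = letters
        if len(cols) >= 3:
            terms = {t for t in cols[2].split(";") if t}
            if terms:
                if dag is not None:
                    missing = terms - dag.terms
                    if missing:
                        raise FormatError(
                            f"{path}:{lineno}: GO terms {sorted(missing)} "
                            f"absent from the DAG"
                        )
                go[pid] = terms
    try:
        return AnnotationSet(cog=cog, go=go)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_annotation_table(annotations: AnnotationSet, path) -> None:
    proteins = sorted(set(annotations.cog) | set(annotations.go))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_id\tcog\tgo\n")
        for pid in proteins:
            cogs = ",".join(annotations.cog.get(pid, []))
            gos = ";".join(sorted(annotations.go.get(pid, set())))
            fh.write(f"{pid}\t{cogs}\t{gos}\n")


def read_expression_table(path) -> ExpressionMatrix:
    """Read an RPKM matrix TSV with a header row of time labels."""
    header: list[str] | None = None
    rpkm: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if header is None:
                cols = line.lstrip("#").split("\t")
                if len(cols) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: header must name >=1 time point"
                    )
                header = cols[1:]
                continue
            if line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(header) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header) + 1} columns, "
                    f"got {len(cols)}"
                )
            values = [
                _parse_float(c, path, lineno, "rpkm") for c in cols[1:]
            ]
            rpkm[cols[0]] = np.asarray(values, dtype=float)
    if header is None:
        raise FormatError(f"{path}: empty expression table")
    return ExpressionMatrix(rpkm=rpkm, time_labels=list(header))


def write_expression_table(expression: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\t" + "\t".join(expression.time_labels) + "\n")
        for pid in sorted(expression.rpkm):
            # repr round-trips doubles exactly, keeping write->read lossless
            vals = "\t".join(repr(float(v)) for v in expression.rpkm[pid])
            fh.write(f"{pid}\t{vals}\n")
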