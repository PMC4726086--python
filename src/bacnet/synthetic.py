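"""Seeded synthetic worlds with planted ground truth.

A world emulates every input the pipeline consumes: a target proteome,
reference organisms with curated interactomes, a planted ortholog map
realized as similarity-search hit tables (true orthologs pass all three
filters; decoys each fail exactly one), domain assignments with an
interacting-domain-pair catalogue, multi-label COG annotations, a small
randomly generated GO DAG with per-protein terms, and a three-time-point
RPKM matrix in which interacting proteins share a latent expression
profile.

The generator also records the exact network the prediction pipeline
must produce (``truth_network``); self-consistency is asserted at
generation time by running the interolog and domain channels on the
world's own tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ddi as ddi_mod
from . import interolog as interolog_mod
from .io_formats import (
    AnnotationSet,
    DomainHit,
    EdgeRecord,
    ExpressionMatrix,
    GoDag,
    HomologyHit,
    canonical_pair,
    merge_edge_records,
    write_annotation_table,
    write_edge_list,
    write_expression_table,
    write_obo_subset,
)
from .network import PPINetwork, merge_networks


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults are desk-scale study conditions.

    300 target proteins against 2 reference organisms with ~80% ortholog
    coverage; 4 dense planted complexes (intra-density 0.9, sizes 5–10)
    plus sparse background edges; interacting pairs share a latent
    3-time-point expression profile with multiplicative noise sigma;
    decoy homology hits each violate exactly one of the three transfer
    thresholds.
    """

    n_target: int = 300
    reference_organisms: tuple[str, ...] = ("orgA", "orgB")
    p_ortholog: float = 0.8
    n_background_edges: int = 250
    p_within_group_edge: float = 0.6
    n_complexes: int = 4
    complex_size_range: tuple[int, int] = (5, 10)
    complex_intra_density: float = 0.9
    p_interolog_channel: float = 0.65
    p_ddi_channel: float = 0.45
    n_decoy_hits_per_kind: int = 20
    n_secondary_hits: int = 30
    n_reference_noise_edges: int = 150
    n_decoy_domain_hits: int = 40
    n_unused_ddis: int = 50
    n_homomeric: int = 2
    functional_signal: bool = True
    expression_noise_sigma: float = 0.2
    p_cog_annotated: float = 0.88
    p_cog_multilabel: float = 0.15
    p_go_annotated: float = 0.85
    fraction_inactive: float = 0.08
    time_labels: tuple[str, ...] = ("11h", "22h", "33h")
    go_dag_depth: int = 5
    go_terms_per_level: int = 6

    def validate(self) -> None:
        if self.complex_size_range[1] * self.n_complexes > self.n_target:
            raise ValueError("planted complexes larger than the proteome")
        if not (0 <= self.p_ortholog <= 1):
            raise ValueError("p_ortholog must be a probability")


COG_LETTERS = list("CDEFGHIJKLMNOPQTUV")  # common bacterial categories


@dataclass
class SyntheticWorld:
    seed: int
    config: WorldConfig
    target_proteins: list[str]
    organism_map: dict[str, str]  # subject prefix -> organism
    homology_hits: list[HomologyHit]
    reference_ppis: list[EdgeRecord]  # sources[0] = organism
    planted_orthologs: dict[tuple[str, str], str]
    domain_hits: list[DomainHit]
    ddis: ddi_mod.DdiSet
    annotations: AnnotationSet
    go_dag: GoDag
    expression: ExpressionMatrix
    planted_complexes: list[list[str]]
    groups: list[list[str]]  # functional groups (complexes + rest)
    truth_network: PPINetwork
    truth_interolog: list[EdgeRecord] = field(default_factory=list)
    truth_ddi: list[EdgeRecord] = field(default_factory=list)


def _make_go_dag(rng: np.random.Generator, config: WorldConfig) -> GoDag:
    terms: set[str] = set()
    edges: dict[str, list[tuple[str, str]]] = {}
    namespace: dict[str, str] = {}
    counter = 1
    leaves: dict[str, list[str]] = {}
    for ns in ("BP", "MF", "CC"):
        levels: list[list[str]] = []
        root = f"GO:{counter:07d}"
        counter += 1
        terms.add(root)
        namespace[root] = ns
        levels.append([root])
        for depth in range(1, config.go_dag_depth):
            width = max(2, int(config.go_terms_per_level * (1 + 0.3 * depth)))
            level: list[str] = []
            for _ in range(width):
                term = f"GO:{counter:07d}"
                counter += 1
                terms.add(term)
                namespace[term] = ns
                n_parents = 1 + int(rng.random() < 0.3)
                parents = rng.choice(
                    len(levels[-1]), size=min(n_parents, len(levels[-1])),
                    replace=False,
                )
                edges[term] = [
                    (
                        levels[-1][int(p)],
                        "is_a" if rng.random() < 0.8 else "part_of",
                    )
                    for p in sorted(parents)
                ]
                level.append(term)
            levels.append(level)
        leaves[ns] = levels[-1]
    dag = GoDag(terms=terms, edges=edges, namespace=namespace)
    dag.validate()
    dag.generated_leaves = leaves  # type: ignore[attr-defined]
    return dag


def _dense_module_edges(
    members: list[str], density: float, rng: np.random.Generator
) -> set[tuple[str, str]]:
    edges: set[tuple[str, str]] = set()
    m = len(members)
    # guarantee connectivity with a path, then fill to the target density
    for i in range(m - 1):
        edges.add(canonical_pair(members[i], members[i + 1]))
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < density:
                edges.add(canonical_pair(members[i], members[j]))
    return edges


def generate_world(seed: int, config: WorldConfig | None = None) -> SyntheticWorld:
    """Build a complete synthetic world; deterministic for (seed, config)."""
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    targets = [f"BL{i:04d}" for i in range(1, config.n_target + 1)]
    organisms = list(config.reference_organisms)
    prefixes = {f"R{chr(65 + i)}_": org for i, org in enumerate(organisms)}
    prefix_of = {org: pfx for pfx, org in prefixes.items()}

    # ---- planted ortholog map -------------------------------------------
    orthologs: dict[tuple[str, str], str] = {}
    for t_idx, target in enumerate(targets):
        for org in organisms:
            if rng.random() < config.p_ortholog:
                orthologs[(target, org)] = f"{prefix_of[org]}{t_idx + 1:04d}"

    # ---- functional groups: planted complexes + partition of the rest ---
    perm = [targets[int(i)] for i in rng.permutation(config.n_target)]
    complexes: list[list[str]] = []
    cursor = 0
    for _ in range(config.n_complexes):
        size = int(rng.integers(*config.complex_size_range, endpoint=True))
        complexes.append(sorted(perm[cursor : cursor + size]))
        cursor += size
    rest = perm[cursor:]
    groups = list(complexes)
    group_size = 8
    for i in range(0, len(rest), group_size):
        chunk = sorted(rest[i : i + group_size])
        if chunk:
            groups.append(chunk)
    group_of = {p: gi for gi, members in enumerate(groups) for p in members}

    # ---- desired target network -----------------------------------------
    desired: set[tuple[str, str]] = set()
    for members in complexes:
        desired |= _dense_module_edges(
            members, config.complex_intra_density, rng
        )
    n_module_edges = len(desired)
    while len(desired) < n_module_edges + config.n_background_edges:
        if rng.random() < config.p_within_group_edge:
            gi = int(rng.integers(0, len(groups)))
            members = groups[gi]
            if len(members) < 2:
                continue
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[int(i)], members[int(j)]
        else:
            i, j = rng.choice(config.n_target, size=2, replace=False)
            a, b = targets[int(i)], targets[int(j)]
        desired.add(canonical_pair(a, b))

    # ---- realize each desired edge through >=1 evidence channel ---------
    reference_edges: list[EdgeRecord] = []
    domain_hits: list[DomainHit] = []
    ddi_pairs: set[tuple[str, str]] = set()
    domain_counter = 1

    def new_domain() -> str:
        nonlocal domain_counter
        d = f"PF{domain_counter:05d}"
        domain_counter += 1
        return d

    def true_domain_hit(protein: str, accession: str) -> DomainHit:
        # values pre-rounded to the precision the fixture writer uses, so
        # write -> read reproduces the in-memory table exactly
        return DomainHit(
            protein_id=protein,
            domain_accession=accession,
            evalue=float(f"{10.0 ** rng.uniform(-30, -6):.3e}"),
            bias=round(float(rng.uniform(0.0, 0.9)), 3),
            score=round(float(rng.uniform(30, 250)), 1),
        )

    interolog_expected: set[tuple[str, str]] = set()
    ddi_expected: set[tuple[str, str]] = set()
    for a, b in sorted(desired):
        use_interolog = rng.random() < config.p_interolog_channel
        use_ddi = rng.random() < config.p_ddi_channel
        if use_interolog:
            common = [
                org
                for org in organisms
                if (a, org) in orthologs and (b, org) in orthologs
            ]
            if not common:
                use_interolog = False
        if not use_interolog and not use_ddi:
            use_ddi = True
        if use_interolog:
            org = common[int(rng.integers(0, len(common)))]
            reference_edges.append(
                EdgeRecord(
                    orthologs[(a, org)], orthologs[(b, org)], set(), [org]
                )
            )
            interolog_expected.add((a, b))
        if use_ddi:
            dm, dn = new_domain(), new_domain()
            domain_hits.append(true_domain_hit(a, dm))
            domain_hits.append(true_domain_hit(b, dn))
            ddi_pairs.add(canonical_pair(dm, dn))
            ddi_expected.add((a, b))

    # ---- homomeric (self-loop) interactions ------------------------------
    self_loops: set[tuple[str, str]] = set()
    mapped = sorted({t for (t, _) in orthologs})
    for k in range(config.n_homomeric):
        if k % 2 == 0 and mapped:
            t = mapped[int(rng.integers(0, len(mapped)))]
            org = next(org for org in organisms if (t, org) in orthologs)
            sub = orthologs[(t, org)]
            reference_edges.append(EdgeRecord(sub, sub, set(), [org]))
            interolog_expected.add((t, t))
        else:
            t = targets[int(rng.integers(0, len(targets)))]
            d = new_domain()
            domain_hits.append(true_domain_hit(t, d))
            ddi_pairs.add((d, d))
            ddi_expected.add((t, t))
        self_loops.add((t, t))

    # ---- homology hit table: true hits, secondary hits, decoys ----------
    homology_hits: list[HomologyHit] = []

    def true_hit(target: str, org: str, subject: str) -> HomologyHit:
        qlen = int(rng.integers(150, 600))
        slen = qlen + int(rng.integers(-20, 21))
        aln = int(np.ceil(0.85 * max(qlen, slen)))
        return HomologyHit(
            query_id=target,
            subject_id=subject,
            subject_organism=org,
            percent_identity=round(float(rng.uniform(35, 95)), 2),
            alignment_length=aln,
            evalue=float(f"{10.0 ** rng.uniform(-50, -10):.3e}"),
            bit_score=round(float(rng.uniform(150, 500)), 1),
            query_length=qlen,
            subject_length=slen,
        )

    for (target, org), subject in sorted(orthologs.items()):
        homology_hits.append(true_hit(target, org, subject))

    ortholog_keys = sorted(orthologs)
    for k in range(min(config.n_secondary_hits, len(ortholog_keys))):
        target, org = ortholog_keys[int(rng.integers(0, len(ortholog_keys)))]
        primary_score = next(
            h.bit_score
            for h in homology_hits
            if h.query_id == target and h.subject_organism == org
        )
        secondary = true_hit(target, org, f"{prefix_of[org]}X{k + 1:04d}")
        secondary = _replace_hit(
            secondary,
            bit_score=round(max(55.0, primary_score - float(rng.uniform(10, 60))), 1),
        )
        homology_hits.append(secondary)

    decoy_idx = 1
    for kind in ("identity", "evalue", "coverage"):
        for _ in range(config.n_decoy_hits_per_kind):
            target = targets[int(rng.integers(0, len(targets)))]
            org = organisms[int(rng.integers(0, len(organisms)))]
            hit = true_hit(target, org, f"{prefix_of[org]}D{decoy_idx:04d}")
            decoy_idx += 1
            if kind == "identity":
                hit = _replace_hit(
                    hit, percent_identity=round(float(rng.uniform(10, 29)), 2)
                )
            elif kind == "evalue":
                hit = _replace_hit(
                    hit, evalue=float(f"{10.0 ** rng.uniform(-4.5, -1):.3e}")
                )
            else:
                hit = _replace_hit(
                    hit,
                    alignment_length=max(1, int(0.4 * hit.query_length)),
                )
            homology_hits.append(hit)

    # ---- reference interactome noise (no transferable endpoints) --------
    for k in range(config.n_reference_noise_edges):
        org = organisms[int(rng.integers(0, len(organisms)))]
        i, j = rng.choice(5000, size=2, replace=False)
        reference_edges.append(
            EdgeRecord(
                f"{prefix_of[org]}N{int(i) + 1:04d}",
                f"{prefix_of[org]}N{int(j) + 1:04d}",
                set(),
                [org],
            )
        )

    # ---- decoy domain hits and unused DDIs -------------------------------
    for k in range(config.n_decoy_domain_hits):
        target = targets[int(rng.integers(0, len(targets)))]
        d = new_domain()
        hit = true_domain_hit(target, d)
        if k % 2 == 0:
            hit = DomainHit(
                hit.protein_id,
                hit.domain_accession,
                evalue=float(f"{10.0 ** rng.uniform(-4.5, -1):.3e}"),
                bias=hit.bias,
                score=hit.score,
            )
        else:
            hit = DomainHit(
                hit.protein_id,
                hit.domain_accession,
                evalue=hit.evalue,
                bias=round(float(rng.uniform(1.1, 3.0)), 3),
                score=hit.score,
            )
        domain_hits.append(hit)
    for _ in range(config.n_unused_ddis):
        ddi_pairs.add(canonical_pair(new_domain(), new_domain()))

    ddis = ddi_mod.DdiSet(ddi_pairs)

    # ---- COG annotations --------------------------------------------------
    cog: dict[str, list[str]] = {}
    home_category = {
        gi: COG_LETTERS[int(rng.integers(0, len(COG_LETTERS)))]
        for gi in range(len(groups))
    }
    uncharacterized: set[str] = set()
    for ci, members in enumerate(complexes):
        # one member per complex left uncharacterized for annotation transfer
        uncharacterized.add(members[int(rng.integers(0, len(members)))])
    for target in targets:
        if target in uncharacterized:
            if rng.random() < 0.5:
                cog[target] = ["S"]
            continue
        if rng.random() >= config.p_cog_annotated:
            continue
        gi = group_of[target]
        if config.functional_signal and rng.random() < 0.85:
            primary = home_category[gi]
        else:
            primary = COG_LETTERS[int(rng.integers(0, len(COG_LETTERS)))]
        cats = [primary]
        if rng.random() < config.p_cog_multilabel:
            extra = COG_LETTERS[int(rng.integers(0, len(COG_LETTERS)))]
            if extra != primary:
                cats.append(extra)
        cog[target] = cats

    # ---- GO DAG and term annotations --------------------------------------
    dag = _make_go_dag(rng, config)
    leaves = dag.generated_leaves  # type: ignore[attr-defined]
    go: dict[str, set[str]] = {}
    home_terms: dict[int, dict[str, str]] = {}
    for gi in range(len(groups)):
        home_terms[gi] = {
            ns: leaves[ns][int(rng.integers(0, len(leaves[ns])))]
            for ns in ("BP", "MF")
        }
    for target in targets:
        if rng.random() >= config.p_go_annotated:
            continue
        terms: set[str] = set()
        if config.functional_signal:
            gi = group_of[target]
            for ns in ("BP", "MF"):
                if rng.random() < 0.9:
                    terms.add(home_terms[gi][ns])
            if rng.random() < 0.2:
                ns = ("BP", "MF")[int(rng.integers(0, 2))]
                terms.add(leaves[ns][int(rng.integers(0, len(leaves[ns])))])
        else:
            for ns in ("BP", "MF"):
                if rng.random() < 0.9:
                    terms.add(leaves[ns][int(rng.integers(0, len(leaves[ns])))])
        if terms:
            go[target] = terms
    annotations = AnnotationSet(cog=cog, go=go)

    # ---- expression -------------------------------------------------------
    n_t = len(config.time_labels)
    group_pattern = {
        gi: rng.normal(0.0, 1.5, size=n_t) for gi in range(len(groups))
    }
    complex_members = {p for members in complexes for p in members}
    rpkm: dict[str, np.ndarray] = {}
    for target in targets:
        if config.functional_signal:
            base_pattern = group_pattern[group_of[target]]
        else:
            base_pattern = rng.normal(0.0, 1.5, size=n_t)
        log2 = (
            rng.uniform(3.0, 6.5)
            + base_pattern
            + rng.normal(0.0, config.expression_noise_sigma, size=n_t)
        )
        values = np.power(2.0, log2)
        if (
            target not in complex_members
            and rng.random() < config.fraction_inactive
        ):
            t_off = int(rng.integers(0, n_t))
            values[t_off] = float(rng.uniform(0.0, 0.99))
        rpkm[target] = np.round(values, 4)
    expression = ExpressionMatrix(rpkm=rpkm, time_labels=list(config.time_labels))

    # ---- run the prediction pipeline for the truth network ---------------
    thresholds = interolog_mod.InterologThresholds()
    filtered = interolog_mod.filter_homology_hits(homology_hits, thresholds)
    omap = interolog_mod.best_hit_per_organism(filtered)
    interolog_edges = interolog_mod.transfer_interactions(omap, reference_edges)
    assignment = ddi_mod.assign_domains(domain_hits)
    ddi_edges = ddi_mod.predict_from_ddi(assignment, ddis)
    truth, _ = merge_networks(interolog_edges, ddi_edges)

    expected_pairs = interolog_expected | ddi_expected
    if truth.edges != expected_pairs:
        raise AssertionError(
            "synthetic world is not self-consistent: pipeline output "
            f"differs from planted truth by "
            f"{truth.edges ^ expected_pairs}"
        )
    return SyntheticWorld(
        seed=seed,
        config=config,
        target_proteins=targets,
        organism_map=prefixes,
        homology_hits=homology_hits,
        reference_ppis=io_sorted_edges(reference_edges),
        planted_orthologs=dict(orthologs),
        domain_hits=domain_hits,
        ddis=ddis,
        annotations=annotations,
        go_dag=dag,
        expression=expression,
        planted_complexes=complexes,
        groups=groups,
        truth_network=truth,
        truth_interolog=interolog_edges,
        truth_ddi=ddi_edges,
    )


def _replace_hit(hit: HomologyHit, **changes) -> HomologyHit:
    data = {
        "query_id": hit.query_id,
        "subject_id": hit.subject_id,
        "subject_organism": hit.subject_organism,
        "percent_identity": hit.percent_identity,
        "alignment_length": hit.alignment_length,
        "evalue": hit.evalue,
        "bit_score": hit.bit_score,
        "query_length": hit.query_length,
        "subject_length": hit.subject_length,
    }
    data.update(changes)
    return HomologyHit(**data)


def io_sorted_edges(records: list[EdgeRecord]) -> list[EdgeRecord]:
    return merge_edge_records(records)


def write_fixtures(world: SyntheticWorld, directory) -> dict:
    """Write every input file of the pipeline plus a ground-truth manifest.

    Re-reading the files reproduces the in-memory tables; the manifest
    records row counts, the organism map, planted complexes and the truth
    network sizes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    hom_path = directory / "homology_hits.tsv"
    with open(hom_path, "w", encoding="utf-8") as fh:
        fh.write(
            "#qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\t"
            "qend\tsstart\tsend\tevalue\tbitscore\tqlen\tslen\n"
        )
        for h in world.homology_hits:
            mismatch = int(h.alignment_length * (100 - h.percent_identity) / 100)
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{mismatch}\t0\t1\t{h.alignment_length}\t"
                f"1\t{h.alignment_length}\t{h.evalue:.3e}\t{h.bit_score:.1f}\t"
                f"{h.query_length}\t{h.subject_length}\n"
            )

    dom_path = directory / "domain_hits.tsv"
    with open(dom_path, "w", encoding="utf-8") as fh:
        fh.write("#protein_id\tdomain_accession\tevalue\tbias\tscore\n")
        for d in world.domain_hits:
            fh.write(
                f"{d.protein_id}\t{d.domain_accession}\t{d.evalue:.3e}\t"
                f"{d.bias:.3f}\t{d.score:.1f}\n"
            )

    ref_path = directory / "reference_ppis.tsv"
    write_edge_list(world.reference_ppis, ref_path)

    ddi_path = directory / "ddi_pairs.tsv"
    ddi_mod.write_ddi_table(world.ddis, ddi_path)

    ann_path = directory / "annotations.tsv"
    write_annotation_table(world.annotations, ann_path)

    obo_path = directory / "go_dag.obo"
    write_obo_subset(world.go_dag, obo_path)

    expr_path = directory / "rpkm.tsv"
    write_expression_table(world.expression, expr_path)

    truth_path = directory / "truth_network.tsv"
    write_edge_list(world.truth_network.records(), truth_path)

    manifest = {
        "seed": world.seed,
        "organism_map": world.organism_map,
        "files": {
            "homology_hits": [hom_path.name, len(world.homology_hits)],
            "domain_hits": [dom_path.name, len(world.domain_hits)],
            "reference_ppis": [ref_path.name, len(world.reference_ppis)],
            "ddi_pairs": [ddi_path.name, len(world.ddis.pairs)],
            "annotations": [
                ann_path.name,
                len(set(world.annotations.cog) | set(world.annotations.go)),
            ],
            "go_dag": [obo_path.name, len(world.go_dag.terms)],
            "rpkm": [expr_path.name, len(world.expression.rpkm)],
            "truth_network": [truth_path.name, world.truth_network.n_edges],
        },
        "planted_complexes": world.planted_complexes,
        "planted_orthologs": {
            f"{t}|{org}": s for (t, org), s in sorted(world.planted_orthologs.items())
        },
        "truth": {
            "n_nodes": world.truth_network.n_nodes,
            "n_edges": world.truth_network.n_edges,
            "n_interolog": len(world.truth_interolog),
            "n_ddi": len(world.truth_ddi),
        },
        "time_labels": list(world.config.time_labels),
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
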