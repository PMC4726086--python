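"""End-to-end orchestration: predict -> merge -> characterize -> validate
-> dynamics -> complexes -> annotate, with a machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import complexes as complexes_mod
from . import ddi as ddi_mod
from . import dynamics as dynamics_mod
from . import enrichment as enrichment_mod
from . import interolog as interolog_mod
from . import mds as mds_mod
from . import validation as validation_mod
from .io_formats import (
    read_annotation_table,
    read_domain_table,
    read_edge_list,
    read_expression_table,
    read_homology_table,
    read_obo_subset,
)
from .network import (
    merge_networks,
    powerlaw_gamma_mle,
    remove_self_loops,
    topology_summary,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    homology_hits: str
    domain_hits: str
    reference_ppis: str
    ddi_pairs: str
    annotations: str
    go_dag: str
    rpkm: str
    organism_map: dict[str, str]
    output_dir: str = "."
    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_coverage: float = 60.0
    domain_max_evalue: float = 1e-5
    domain_max_bias: float = 1.0
    rpkm_threshold: float = 1.0
    clustering_lambda: float = 1.0
    min_complex_size: int = 3
    n_random: int = 20
    alpha: float = 0.05
    seed: int = 0
    mds_time_limit: float = 600.0
    category_groups: list[str] = field(default_factory=lambda: ["E", "P"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @classmethod
    def from_fixture_dir(cls, directory, **overrides) -> "RunConfig":
        """Configuration pointing at a fixture directory written by
        :func:`bacnet.synthetic.write_fixtures`."""
        directory = Path(directory)
        with open(directory / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        base = dict(
            homology_hits=str(directory / "homology_hits.tsv"),
            domain_hits=str(directory / "domain_hits.tsv"),
            reference_ppis=str(directory / "reference_ppis.tsv"),
            ddi_pairs=str(directory / "ddi_pairs.tsv"),
            annotations=str(directory / "annotations.tsv"),
            go_dag=str(directory / "go_dag.obo"),
            rpkm=str(directory / "rpkm.tsv"),
            organism_map=manifest["organism_map"],
            output_dir=str(directory),
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        for attr in (
            "homology_hits",
            "domain_hits",
            "reference_ppis",
            "ddi_pairs",
            "annotations",
            "go_dag",
            "rpkm",
        ):
            path = Path(getattr(self, attr))
            if not path.exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, write_report: bool = True) -> dict:
    """Execute every stage in order and return the run report."""
    config.validate()
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # propagate with stage context
            raise StageError(name, exc) from exc

    # --- inputs -----------------------------------------------------------
    dag = stage("read_go_dag", lambda: read_obo_subset(config.go_dag))
    annotations = stage(
        "read_annotations", lambda: read_annotation_table(config.annotations, dag)
    )
    expression = stage(
        "read_expression", lambda: read_expression_table(config.rpkm)
    )
    hits = stage(
        "read_homology",
        lambda: read_homology_table(config.homology_hits, config.organism_map),
    )
    domain_hits = stage(
        "read_domains", lambda: read_domain_table(config.domain_hits)
    )
    reference = stage(
        "read_reference_ppis", lambda: read_edge_list(config.reference_ppis)
    )
    ddis = stage("read_ddis", lambda: ddi_mod.read_ddi_table(config.ddi_pairs))

    # --- prediction channels ---------------------------------------------
    def interolog_channel():
        thresholds = interolog_mod.InterologThresholds(
            max_evalue=config.max_evalue,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
        )
        filtered = interolog_mod.filter_homology_hits(hits, thresholds)
        omap = interolog_mod.best_hit_per_organism(filtered)
        return interolog_mod.transfer_interactions(omap, reference)

    interolog_edges = stage("interolog", interolog_channel)
    ddi_edges = stage(
        "ddi",
        lambda: ddi_mod.predict_from_ddi(
            ddi_mod.assign_domains(
                domain_hits, config.domain_max_evalue, config.domain_max_bias
            ),
            ddis,
        ),
    )

    merged, merge_report = stage(
        "merge", lambda: merge_networks(interolog_edges, ddi_edges)
    )
    report["channels"] = {
        "interolog_edges": merge_report.n_channel_a,
        "ddi_edges": merge_report.n_channel_b,
        "shared_edges": merge_report.n_shared,
        "merged_edges": merge_report.n_union,
        "merged_nodes": merged.n_nodes,
    }

    reduced, loop_report = stage("remove_self_loops", lambda: remove_self_loops(merged))
    report["self_loops"] = {
        "removed": loop_report.n_self_loops_removed,
        "nodes_dropped": loop_report.n_nodes_dropped,
        "nodes": reduced.n_nodes,
        "edges": reduced.n_edges,
    }

    # --- topology ---------------------------------------------------------
    summary = stage("topology", lambda: topology_summary(reduced))
    degrees = [m.degree for m in summary.per_node.values()]
    try:
        fit = powerlaw_gamma_mle(degrees)
        gamma = {"continuous": fit.gamma, "discrete": fit.gamma_discrete}
    except ValueError:
        gamma = None
    report["topology"] = {
        "n_nodes": summary.n_nodes,
        "n_edges": summary.n_edges,
        "average_degree": summary.average_degree,
        "average_path_length": summary.average_path_length,
        "clustering_coefficient": summary.clustering_coefficient,
        "n_components": summary.n_components,
        "largest_component_nodes": summary.largest_component_nodes,
        "largest_component_edges": summary.largest_component_edges,
        "gamma_mle": gamma,
    }

    # --- controllability --------------------------------------------------
    mds_result = stage(
        "mds", lambda: mds_mod.solve_mds_ilp(reduced, config.mds_time_limit)
    )
    mds_enrichment = stage(
        "mds_enrichment",
        lambda: enrichment_mod.fisher_enrichment(
            mds_result.members & reduced.nodes, reduced.nodes, annotations,
            config.alpha,
        ),
    )
    report["mds"] = {
        "size": mds_result.size,
        "fraction_of_nodes": mds_result.size / reduced.n_nodes,
        "optimal": mds_result.optimal,
        "enriched_categories": sorted(
            r.category for r in mds_enrichment if r.enriched
        ),
    }

    # --- heat map ---------------------------------------------------------
    heatmap = stage(
        "cog_heatmap", lambda: enrichment_mod.cog_heatmap(reduced, annotations)
    )
    report["cog_heatmap"] = {
        "n_annotated": heatmap.n,
        "n_interactions": heatmap.N,
        "categories": heatmap.categories,
        "max_diagonal_z": float(np.nanmax(np.diag(heatmap.z)))
        if heatmap.categories
        else None,
    }

    # --- validation -------------------------------------------------------
    go_test = stage(
        "go_validation",
        lambda: validation_mod.compare_with_random(
            reduced, annotations, dag, n_random=config.n_random, seed=config.seed
        ),
    )
    pcc_test = stage(
        "pcc_validation",
        lambda: validation_mod.transcription_pcc_validation(
            reduced, expression, n_random=config.n_random, seed=config.seed + 1
        ),
    )
    report["validation"] = {
        "go_similarity_p": go_test.p_value,
        "pcc_p": pcc_test.p_value,
        "n_random": config.n_random,
    }

    # --- dynamics ---------------------------------------------------------
    conditions = stage(
        "conditions",
        lambda: complexes_mod.build_time_series_networks(
            reduced, expression, config.rpkm_threshold
        ),
    )
    topo_cmp = stage(
        "local_topology_comparison",
        lambda: dynamics_mod.compare_local_topology(conditions),
    )
    groups = ["control", "all_ppi"] + [
        f"category:{c}" for c in config.category_groups
    ]
    diff = {}
    for cond in conditions:
        dists = stage(
            f"difference_distributions[{cond.time_label}]",
            lambda c=cond: dynamics_mod.difference_distributions(
                c, expression, annotations, groups, seed=config.seed
            ),
        )
        diff[cond.time_label] = {
            d.group: {"median": None if d.empty else d.median, "n": len(d.values)}
            for d in dists
        }
    report["dynamics"] = {
        "active_nodes": {c.time_label: len(c.active_nodes) for c in conditions},
        "topology_min_p": {
            metric: min(t.p_value for t in tests.values())
            for metric, tests in topo_cmp.items()
        },
        "normalized_difference": diff,
    }

    # --- complexes and annotation ----------------------------------------
    complex_set = stage(
        "complexes",
        lambda: complexes_mod.detect_complexes(
            conditions, config.clustering_lambda, config.min_complex_size
        ),
    )
    scores = stage(
        "complex_entropy",
        lambda: complexes_mod.score_complexes(complex_set, annotations),
    )
    assigned = stage(
        "annotate_uncharacterized",
        lambda: enrichment_mod.annotate_uncharacterized(
            complex_set.complexes, annotations, reduced.nodes, config.alpha
        ),
    )
    report["complexes"] = {
        "n_complexes": len(complex_set.complexes),
        "median_entropy": scores.median_entropy,
        "low_entropy_fraction": scores.low_entropy_fraction,
        "n_annotated_uncharacterized": len(assigned),
        "assignments": dict(sorted(assigned.items())),
    }

    if write_report:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    return report
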