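# bacnet

Genome-scale prediction and characterization of bacterial protein–protein
interaction (PPI) networks, built around the two classic computational
transfer methods and the downstream analyses used to judge and exploit the
resulting network.

The package is aimed at computational biologists who have a bacterial
proteome (e.g. *Bacillus licheniformis* WX-02), similarity-search hits
against reference organisms with curated interactomes, profile-HMM domain
assignments, and RNA-seq expression profiles — and who want a predicted
interactome together with evidence provenance, quality assessment, and
function-level analysis, without depending on live database downloads.

## What it computes

**Prediction.** Two independent evidence channels, merged into one
non-redundant network:

* *Interolog transfer* — protein pairs whose orthologs in a reference
  organism interact experimentally. Ortholog candidates are similarity-search
  hits filtered at E-value ≤ 10⁻⁵, identity ≥ 30% and alignment coverage
  ≥ 60%; when a protein matches several proteins of one organism only the
  highest bit-score hit is kept.
* *Domain-pair transfer* — protein pairs (X, Y) carrying domains m ∈ X,
  n ∈ Y with an experimentally or structurally determined domain–domain
  interaction (iPfam/3did-style catalogue). Domains are profile-HMM hits
  filtered at E-value ≤ 10⁻⁵ and bias ≤ 1.

**Characterization.**

* Topology: degree, clustering coefficient (mean over nodes of degree ≥ 2),
  average shortest-path length over connected pairs, betweenness, closeness,
  components; maximum-likelihood degree exponent γ (continuous closed form
  `γ = 1 + n [Σ ln(kᵢ/k_min)]⁻¹` and the discrete zeta-likelihood MLE,
  reported side by side).
* Controllability: a minimum dominating set (MDS) by exact integer linear
  programming (`min Σ xᵥ  s.t.  xᵥ + Σ_{u∈N(v)} xᵤ ≥ 1`), plus greedy and
  exhaustive baselines, with COG enrichment of the MDS members.
* COG-pair heat map: observed class-pair interaction counts A_ij against a
  binomial null with `P_ij = f_i f_j / T` (i ≠ j), `P_ii = f_i(f_i−1)/2 / T`,
  `T = n(n−1)/2`, scored as `Z_ij = (A_ij − N·P_ij)/√(N·P_ij(1−P_ij))`.
* Validation: edge-wise GO functional similarity (Wang graph-based term
  similarity with best-match averaging) and transcription-profile Pearson
  correlation, each compared against pooled degree-preserving rewirings by
  the Wilcoxon rank-sum test.
* Dynamics: per-time-point active subnetworks (RPKM ≥ 1 rule), five local
  topology metrics compared across conditions, and the normalized
  transcription difference `D_ij = |RPKM_i − RPKM_j| / (RPKM_i + RPKM_j)`
  for control / interacting / category-restricted pair groups.
* Complexes: greedy density clustering on time-series subnetworks
  (parameters: RPKM threshold 1, λ = 1, minimum size 3), functional-category
  entropy `H_i = −Σ_j (F_ij/n_i) log₂(F_ij/n_i)`, and Fisher-enrichment-based
  annotation of uncharacterized (no-COG or S/R) complex members.

**Synthetic worlds.** `bacnet.synthetic` generates complete seeded test
universes — proteome, reference interactomes, hit tables with decoys that
each fail exactly one filter, domain catalogues, COG/GO annotations over a
generated DAG, and correlated 3-time-point expression — with the planted
truth network recorded, so the whole pipeline is testable offline.

## Worked example

```
$ bacnet make-fixtures --seed 7 --out fixtures/
world seed=7: 314 truth edges, 253 nodes -> fixtures/
$ bacnet run --fixtures fixtures/ --n-random 20
merged 314 edges; report in fixtures/run_report.json
```

The report contains, among other things:

```json
"channels": {"interolog_edges": 161, "ddi_edges": 218, "shared_edges": 65,
             "merged_edges": 314, "merged_nodes": 253},
"self_loops": {"removed": 2, "nodes_dropped": 1, "nodes": 252, "edges": 312},
"topology": {"average_degree": 2.476, "average_path_length": 10.217,
             "clustering_coefficient": 0.173, "n_components": 8, ...},
"mds": {"size": 82, "fraction_of_nodes": 0.325, "optimal": true, ...},
"validation": {"go_similarity_p": 1.89e-40, "pcc_p": 5.30e-44, "n_random": 20}
```

Reading: the two channels predicted 161 and 218 edges sharing 65, the merged
network reproduces the generator's planted truth exactly (314 edges), two
homomeric interactions were set aside before topology, an exact minimum
dominating set covers 33% of nodes, and both validation signals (GO
similarity and expression correlation of interacting pairs) are far beyond
what degree-matched rewired networks produce — as expected on a world with
planted functional signal.

Every subcommand is also available separately (`predict-interolog`,
`predict-ddi`, `merge`, `topology`, `mds`, `heatmap`, `enrich`, `validate`,
`dynamics`, `complexes`, `report`); `bacnet <cmd> --help` shows the file
formats.

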