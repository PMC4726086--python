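# Methods

This note records the models implemented in `bacnet`, the conventions and
numerical choices behind them, what the synthetic worlds do and do not
emulate, and the design decisions made where the underlying methodology
left genuine freedom.

## Interaction transfer

**Interolog channel.** A target pair (A, B) is predicted to interact when
A and B have orthologs a, b *in the same reference organism* and (a, b) is
an experimentally determined interaction there. Requiring a single
supporting organism (rather than allowing a and b from different species)
is deliberate: curated interactions are organism-specific observations and
mixing species would manufacture support no experiment provides.

Ortholog candidates are one-directional best hits. Filters: E-value ≤ 1e-5,
identity ≥ 30%, coverage ≥ 60%. "Coverage" is ambiguous in much of the
interolog literature; we use the stricter symmetric reading —
`min(alignment/query_length, alignment/subject_length) ≥ 60%` — which
suppresses partial-domain matches masquerading as orthologs. A
`coverage_mode="query"` switch restores the query-only reading. When one
query matches several proteins of one organism, the highest **bit score**
wins (raw alignment scores are not comparable across searches); ties break
by smaller E-value, then lexicographically smaller subject id, so the map
is deterministic.

**Domain channel.** Domains are profile-HMM hits kept at full-sequence
E-value ≤ 1e-5 and bias ≤ 1 (the bias cap guards against composition-driven
hits). A single catalogued interacting domain pair suffices for a
prediction; all supporting pairs are recorded as evidence weight but not
used for filtering, since any threshold on support count would be an
uncalibrated free parameter.

**Homomeric interactions** (self-loops) are produced by both channels and
flagged; every downstream topological analysis runs after
`remove_self_loops`, because degree-based statistics and rewiring nulls are
ill-defined with loops. The merge step is a plain evidence-union of the two
channels' canonical edge sets; `|A∪B| = |A|+|B|−|A∩B|` is asserted on every
merge.

## Topology conventions

The statistics follow the conventions of the NetworkAnalyzer family of
tools, which matter on fragmented networks:

* average shortest-path length averages over **connected ordered pairs
  only**, so it is finite on a multi-component graph;
* the network clustering coefficient averages node clustering over nodes of
  degree ≥ 2 (degree-0/1 nodes carry no triangle information); a flag
  includes them as zeros;
* closeness of v is |reachable(v)| / Σ d(v, u) within v's component;
  betweenness is normalized by (n−1)(n−2)/2 over the whole graph.

**Degree exponent.** Two maximum-likelihood estimators are always reported
side by side: the continuous closed form γ = 1 + n [Σ ln(kᵢ/k_min)]⁻¹ and
the discrete estimator that numerically maximizes the Hurwitz-zeta
likelihood (bounded search on (1.0001, 12)). At k_min = 1 on genuinely
discrete degrees the continuous form is known to be biased upward; we keep
it because it is the form most network papers quote, and the discrete value
is the statistically defensible one. `sample_powerlaw_degrees` draws from
the exact zeta law (rejection below k_min), and the discrete MLE recovers a
planted γ = 2.5 within ±0.1 at n = 10,000 — the continuous form on the same
sample does not, which is precisely the documented bias.

**Null model.** "Random networks with the same topology" is implemented as
degree-preserving double-edge-swap rewiring: 10·|E| successful swaps by
default, rejecting swaps that would create loops or multi-edges, attempts
capped at 10× the target so swap-free graphs (e.g. a triangle) terminate
unchanged. Seeded and fully deterministic. A configuration-model
alternative exists behind `configuration_model_null` but collapses
multi-edges, so degrees are only approximately preserved; rewiring is the
default everywhere.

## Minimum dominating set

Domination is closed-neighborhood (a node covers itself), which makes the
covering constraint satisfiable on isolated nodes and matches the network-
controllability literature. The ILP is solved exactly with HiGHS
branch-and-bound via `scipy.optimize.milp`; solutions are verified by an
independent domination checker before being returned, and on graphs of
≤ 16 nodes the ILP is tested against exhaustive subset enumeration. MDSs
are generally non-unique: only the *size* is a model output; any analysis
of MDS membership (e.g. COG enrichment of MDS members) is solution-
dependent and is reported as such.

## COG-pair heat map

Among the n COG-annotated network proteins there are T = n(n−1)/2 pairs;
placing N interactions at random gives class pair (i, j) a Binomial(N, P_ij)
count with P_ij = f_i f_j / T (i ≠ j) and P_ii = f_i(f_i−1)/2 / T. The
Z-score standardizes the observed count by that null mean and variance.
Conventions: N counts only edges whose two endpoints are COG-annotated
(unannotated proteins cannot contribute to any cell, so they are excluded
from n as well); a multi-label protein counts once in every f_i it belongs
to, and an edge contributes one count to each distinct unordered category
combination of its endpoints. Cells with P_ij ∈ {0, 1} have undefined
Z-scores and are reported as missing rather than ±∞.

## Functional similarity and validation

Term similarity is the Wang graph-based measure: the S-value of an ancestor
t of term A is the maximal product of edge weights along a path from A to t
(is_a 0.8, part_of 0.6, S_A(A) = 1), and
sim(A,B) = Σ_{t∈anc(A)∩anc(B)} (S_A(t)+S_B(t)) / (SV(A)+SV(B)). Protein
similarity combines the term matrix by best-match averaging per namespace
and averages over the namespaces in which both proteins are annotated;
pairs with no shared annotated namespace are skipped and counted. The
measure is pluggable — any term-level function with the same signature can
replace Wang's.

Edge-level distributions (GO similarity; Pearson correlation of RPKM
profiles, zero-variance profiles skipped) are compared against the pooled
edge values of seeded rewired networks. Pooling all rewired edges into one
sample (the default, `n_random` networks) uses all information; per-network
summaries would be more conservative but discard most of it. The
comparison is a Wilcoxon rank-sum test, alternative "greater" for the
predicted network. The test statistic is the midrank sum of the first
sample; P-values are exact by enumeration when n_x+n_y ≤ 12 without ties,
otherwise a normal approximation with tie and continuity corrections.
Correlation over three time points is statistically weak per pair — the
comparison is meaningful only in aggregate over hundreds of edges, which is
exactly how it is used.

## Dynamics

A gene with RPKM < 1 at a time point is inactive there and is removed with
its edges; proteins missing from the expression table count as inactive
(the removal rule is the only stated mechanism, so absence of evidence is
treated as absence). The "control" group of the normalized-difference
analysis is all unordered pairs of *active* nodes; above 10⁶ pairs a seeded
uniform subsample is drawn so the quadratic set stays tractable. Category
subnetworks require **both** endpoints to carry the category letter.
Condition comparisons run the two-sided rank-sum test per node-level metric
(degree, clustering, average shortest path, betweenness, closeness);
conditions with fewer than 3 active nodes are excluded.

## Complex detection

The detector is a fully specified greedy density clustering on time-series
subnetworks — a deterministic stand-in for published time-series complex
discovery algorithms, sharing their interface (interactions + expression;
parameters RPKM threshold 1, λ = 1, minimum size 3) but not reproducing any
of them bit-for-bit. Per time point: seeds are unassigned nodes in
decreasing degree order (lexicographic tie-break); the cluster repeatedly
absorbs the frontier node with the most links into the cluster (ties:
higher degree, then lexicographic), accepted while links ≥ λ·|C|/2; closed
clusters of size ≥ min_size claim their members. λ enters only through this
acceptance ratio. Across time points, clusters with overlap score
|A∩B|²/(|A|·|B|) ≥ 0.8 are merged to a fixpoint; 0.8 is the conventional
overlap threshold of the complex-matching literature and is a documented
free parameter. Every reported complex is connected in at least one
time-series subnetwork (asserted in tests).

Entropy uses each member's primary (first-listed) COG category, or
"unknown" when unannotated, so the counts F_ij sum to the member count and
H = −Σ (F_ij/n_i) log₂(F_ij/n_i) is bounded by log₂(categories present).
An all-unknown complex has entropy 0 and is flagged rather than treated as
homogeneous evidence. Function transfer assigns the most-enriched
informative category (one-sided Fisher, raw P < α; S/R excluded as
assignable categories) of a complex to its uncharacterized members (empty
COG or only S/R); a protein in several enriched complexes keeps the
smallest-P assignment. Raw P drives the enrichment flag to match the
conventional P < 0.05 usage; Benjamini–Hochberg adjusted values are always
reported alongside for readers who want FDR control.

## Synthetic worlds

Defaults are desk-scale study conditions chosen so the full pipeline,
including the exact ILP, runs in seconds: 300 target proteins, 2 reference
organisms at 80% ortholog coverage, 4 planted dense modules (sizes 5–10,
intra-density 0.9) over ~250 background edges (60% drawn within functional
groups), ~60 homology decoys each violating exactly one filter, secondary
lower-scoring homologs to exercise best-hit reduction, reference-interactome
noise among non-orthologous proteins, unused domain pairs and
threshold-failing domain hits, 85–88% COG/GO annotation coverage, and
3-time-point expression in which each functional group shares a latent
log-profile with multiplicative noise σ = 0.2 (8% of non-module proteins
are deactivated at one time point to exercise the RPKM rule).

Ground truth is exact by construction: each planted edge is realized
through the interolog channel (a same-organism reference edge between the
planted orthologs), the domain channel (a dedicated interacting domain
pair), or both; decoys and noise are constructed so they cannot generate
edges. The generator re-runs the actual prediction code at generation time
and asserts that the output equals the planted truth, and fixture files
round-trip losslessly (numeric fields are pre-rounded to the written
precision).

What the worlds do **not** emulate: real sequence content and hence real
similarity-score distributions, realistic Pfam domain architectures
(dedicated domain pairs per edge avoid cross-talk by design, whereas real
promiscuous domains create correlated false positives), the true GO DAG
(a random 3-namespace DAG of depth 5 stands in), genome-scale network size,
and RNA-seq count noise. Passing tests therefore demonstrate correctness of
the algorithms and the detectability of planted signal under the stated
conditions — not the biological accuracy of any real predicted network.

## Degenerate inputs and tie-breaking

All unordered pairs are stored canonically (lexicographic); every
tie-break in the package (best hit, greedy MDS, cluster seeding and
absorption, exhaustive MDS) ends in lexicographic order, making every
result deterministic for fixed inputs and seeds. Readers reject malformed
rows with line numbers rather than coercing. Empty networks are errors for
topology, size-0 results for MDS; degenerate power-law samples (all degrees
at k_min) raise instead of returning an infinite exponent; identical
samples give rank-sum P = 1.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
worlds: the default 300-protein world for end-to-end checks, 20 seeds for
self-consistency and planted-module recovery (recovery threshold: ≥ 80% of
modules at overlap ≥ 0.5), 60-protein null worlds × 100 seeds for type-I
control of the validation comparisons (each against 20 rewired networks),
200 random graphs of ≤ 16 nodes for ILP-vs-exhaustive equivalence, and
n = 10,000 samples for degree-exponent recovery. These sizes are the
package's own reproducibility conditions; all scale linearly upward through
`WorldConfig`.
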