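# Methods

This note documents the models, conventions and design choices behind
`hicnet`, in the order a user meets them: the data model, ingest, the
exploration semantics, the analytics conventions, comparison statistics,
the omics overlay, and the synthetic generator used throughout the tests.

## Data model

A `MultiExperimentGraph` holds genes and contacts. A **gene** is a symbol
plus a genomic interval in BED convention (0-based, half-open); the symbol
is the identity key, so inserting the same symbol twice returns the same
node, and the same symbol with a *different* interval is a hard error — a
silent merge of two loci sharing a name would corrupt every downstream
neighbourhood. A **contact** is an unordered gene pair within one
experiment, carrying an integer read-count weight (≥ 1), a probability in
(0, 1], and an open property set for whatever extra columns the input had.

Conventions that needed a decision:

* **Undirected everywhere.** Upstream tools may emit directed records, but
  read pairs carry no meaningful orientation for spatial proximity; input
  direction is dropped on ingest.
* **Duplicate aggregation.** A second record for the same pair in the same
  experiment adds its weight (read support is additive evidence) and keeps
  the maximum probability; properties merge with the newer record winning.
* **Self-contacts rejected.** A gene-proximity graph has no use for
  self-loops.
* **Auto-registration.** Unknown experiment labels register themselves on
  first contact insertion (ingest convenience); `strict=True` disables
  this.
* **Counts are derived, never stored.** `Experiment.n_genes`/`n_edges` are
  recomputed from the contact partition on access, so they cannot drift;
  the on-disk store declares them and `load` verifies the declaration.

Persistence is three TSV files (genes, experiments, edges) with sorted
rows, so saving the same store twice is byte-identical. Edge properties
serialise as `key=value;…` with int/float/str re-typing on parse; property
keys and values may not contain tab, `;`, `=` or newline (enforced on
write). A numeric-looking string property therefore comes back as a
number — acceptable for this format's purpose (round-tripping scalar edge
annotations).

## Ingest and export

The canonical contact dialect is declared by this package (column layout
in the README); a `column_map` argument adapts variant headers. Strand in
BED6+ input is ignored throughout — contacts are spatial, not stranded.

Binned matrices convert to gene-pair edges by summing counts over
unordered bin pairs `{i, j}`, `i ≠ j`, where one bin overlaps each gene;
each unordered bin pair contributes once, so a gene spanning several bins
accumulates all of them without double counting. Matrix-derived edges get
probability 1.0 (matrices carry none) and the property `source=matrix`, so
probability-weighted path analyses can recognise and, if desired, exclude
them (a `-log₂ 1.0 = 0` edge length would otherwise make them free hops).

The graph-database export writes bulk-import CSVs: a gene node file keyed
by symbol, a per-experiment summary file, and an edge file whose
relationship type is the experiment name uppercased with non-alphanumerics
mapped to `_` (`T0_Rep1 → T0_REP1`). Exact headers are constants in
`hicnet.io` and in the docstring of `write_neo4j_import`. Only the
bulk-import format is emitted; no live database is contacted.

## Exploration

A session is an immutable tuple of steps; a step is (anchor genes,
experiment filter, weight threshold). Resolving unions, per step, the
anchors with their threshold-passing neighbours and the qualifying
anchor–neighbour edges. Because sessions are values, `expand` returns a
new session, `step_back` drops the last step, and `truncate_at_edge`
rewinds to the first step that introduced an edge; `resolve` is a pure
function of (session, store, flags) with sorted insertion order, so
repeated resolutions are identical.

Open semantics settled here:

* **Threshold scope.** `set_threshold` edits the *latest* step (each step
  remembers its own threshold, mirroring how a user tightens the view as
  it grows); `all_steps=True` applies it session-wide.
* **Experiment filter.** Default is union across selected experiments; a
  `require_all_experiments` flag keeps only neighbours with a qualifying
  edge in *every* selected experiment (the sharpened-query behaviour).
* **Threshold filters weight**, not probability; a separate
  `min_probability` option exists but defaults off.
* `render_pattern` serialises a session as one Cypher-style `MATCH` clause
  per step, for provenance and debugging only.

## Analytics conventions

Standard algorithms follow fixed, documented conventions because more
than one exists in the field; where a flag is named, the non-default
variant is available.

* **Modularity/Louvain**: weighted Newman modularity
  `Q = Σ_c [W_in(c)/m − γ (S_c/2m)²]` with read-count weights by default
  (`weighted=False` for topology only). The reported modularity is this
  direct formula evaluated on the returned membership, not a by-product of
  the optimiser, so it is exactly recomputable. The sweep order is
  shuffled by the mandatory seed; community ids are assigned by each
  community's lexicographically smallest member, making output
  deterministic under a fixed seed.
* **PageRank**: power iteration on the undirected graph, each edge acting
  as two arcs, contributions proportional to edge weight; stop when the L1
  change drops below `tol` (default 1e-9, `max_iter` 200, error carrying
  the iteration count otherwise). Vertices with no edges pass nothing on
  and receive teleport-only (renormalised) mass; values sum to one.
* **Betweenness**: unnormalised pair counts, endpoints excluded, each
  unordered pair counted once; `weighted=True` uses `1/weight` as distance
  (heavier contact ⇒ spatially closer).
* **Closeness**: component-restricted `c(v) = (n_v − 1)/Σ d(v, u)` with
  `n_v` the component size; isolated vertices score 0. Harmonic closeness
  behind `harmonic=True`.
* **Paths**: `hops` mode is unit lengths; `probability` mode minimises
  `Σ −log₂ p`, i.e. maximises the product of edge probabilities, with
  length reported in bits. Ties break lexicographically on the gene-symbol
  path, so results are deterministic. An unreachable pair is an explicit
  unreachable result, not an exception.
* **Per-gene Jaccard** across two experiments uses threshold-passing
  neighbour sets; two *empty* sets score 1.0 — identical absence of
  contacts is agreement. This convention matters for sparse experiments
  and is deliberate and prominent.

Implementation note: betweenness, closeness, local clustering and the
Louvain sweep delegate to networkx; modularity evaluation, PageRank and
the path routines are implemented here because the conventions above
(direct-formula modularity, L1 stopping + teleport-only edgeless vertices,
lexicographic path tie-breaks) are part of the package contract. The test
suite checks all of them against independent recomputations
(Floyd–Warshall path-count DP, simple-path enumeration, triple
enumeration, dense linear solves) on exhaustive ≤ 7-vertex graph
enumerations and seeded random graphs.

## Comparison

Experiment-level Jaccard compares unordered gene-pair edge *sets*,
ignoring weights (a weighted min/max-ratio variant sits behind a flag).
It is reported as similarity — unit diagonal, symmetric — and the matrix
builder enforces that structure by construction. Partition agreement is
the adjusted Rand index on the shared gene set (warning if the inputs'
gene sets differ). Metric deltas inner-join two experiments' metric maps
and sort by |Δ| descending with a symbol tie-break.

## Omics overlay

`classify_direction` splits a gene→value table at a threshold (default 0):
strictly above → over, strictly below → under, exactly at the threshold →
excluded but counted. `metric_by_group` computes the metric map once per
experiment, drops group genes absent from the subgraph (reporting the
count), and reports per-group mean, sample (n−1) variance and standard
deviation plus a Welch two-sample t statistic (positive when the over
group scores higher).

Two p-value conventions: the default is the standard two-sided Welch test
(Welch–Satterthwaite df). The `paper_compat` convention evaluates the same
t statistic against a reference t distribution with **one** degree of
freedom — closed form `p = 2(½ − arctan|t|/π)` — which reproduces the
(t, p) pairs of some published group-comparison tables in this area. It is
flagged as a compatibility quirk: with df = 1 the reference distribution
is Cauchy, making the test extremely conservative, and it should not be
used for new analyses.

On "clustering attitude": the local clustering tendency of a vertex can be
reported either as the [0,1] clustering coefficient or as the raw triangle
count; published tables are ambiguous between (possibly scaled) variants,
so both metrics are exposed (`clustering_coefficient`, `triangles`) and
the caller picks. No claim is made that either reproduces any particular
published table's absolute scale.

## Synthetic data

The generator emulates the *structure* of a gene-centric Hi-C study, not
its biophysics:

* Genes laid out sequentially per chromosome; lengths lognormal (median
  20 kb, σ=0.5 in log-space), 5 kb gaps — plausible gene-scale geometry.
* Intra-chromosomal contact probability `intra_base·(1+d)^−α` at gene-index
  distance `d`, default α = 1.1 — contact frequency in real data decays
  approximately as a power law with exponent near 1 at this scale — with
  `intra_base = 0.5`; inter-chromosomal contacts at a flat 0.002.
* Weights geometric (p = 0.5): mode 1 and a long tail, like read-support
  counts; probabilities uniform on (0.05, 1].
* Defaults of 250 genes on 5 chromosomes keep every test and the
  acceptance script fast while leaving non-trivial topology.

`perturb_experiment` removes `⌊f·E⌋` random edges and adds the same number
of fresh pairs (never colliding with the base edge set), so edge-set
Jaccard against the base is `(E−r)/(E+r)` — in expectation
`(1−f)/(1+f)` — which gives the comparison layer a closed-form target.
`planted_partition_experiment` produces contiguous ground-truth blocks
with within/between edge probabilities `p_in > p_out`. Recovery tests run
Louvain *unweighted*: the planted truth is topological and the generated
weights are independent nuisance draws.

What the synthetic data does **not** model: restriction-fragment bias, TAD
hierarchy, compartment structure, mappability, replicate-specific noise
correlations. Passing tests therefore demonstrate algorithmic correctness
and contract stability, not biological validity on real Hi-C.

## Numerical choices

Floating-point path lengths compare with a 1e-12 tie tolerance; PageRank
convergence is L1 < 1e-9; modularity equality in tests is 1e-12;
probabilities serialise via `repr` for exact round trips. Degenerate
inputs have defined behaviour throughout: empty graphs are legal for every
centrality except Louvain (which needs an edge) and PageRank (which needs
a vertex); empty experiments resolve to empty subgraphs; an all-one-sided
overlay classification warns rather than fails.

## Known limitations

No live graph-database round trip (only the bulk-import format is
emitted); no `.hic`/`.cool` binary adapters (text matrices only); edge
property values are scalars; the store is single-threaded and in-memory;
link prediction is out of scope.
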