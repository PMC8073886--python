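# hicnet

Gene-centric, multi-experiment Hi-C contact graphs for Python: a compact
store, progressive exploration, graph analytics, cross-experiment
comparison and omics overlays.

## The problem

Hi-C (genome-wide chromosome conformation capture) reports which genomic
regions sit close together in the nucleus. The usual representation is a
binned contact matrix `X` with `X_ij` the number of read pairs linking bins
`i` and `j`. That view is fine for one or two chromosomes but awkward for
the *neighbourhood of a gene*, which can span many chromosomes. The
gene-centric alternative is a graph: vertices are genes, an edge is a Hi-C
contact whose supporting read count is the edge weight (a proxy for
physical closeness), optionally with a per-edge probability score from the
upstream graph builder.

`hicnet` manages several such graphs at once — time points, replicates,
conditions — with each gene stored exactly once and contact edges
partitioned by experiment label, and makes three kinds of question cheap:

1. **Exploration** — grow the neighbourhood of a gene one step at a time,
   with a weight threshold, where the whole navigation state is an
   immutable, serialisable session (so any view is reproducible from a
   small JSON document).
2. **Analytics** — per experiment: degree distributions, local clustering
   ("clustering attitude"), Louvain communities on weighted modularity

   `Q = Σ_c [ W_in(c)/m − (S_c / 2m)² ]`,

   PageRank, betweenness and closeness centralities, hop- or
   probability-weighted shortest paths (edge length `−log₂ p`, so the
   shortest path is the most probable one), and per-gene neighbour Jaccard
   across two experiments.
3. **Comparison & overlays** — edge-set Jaccard similarity matrices
   between experiments, community profiles and partition agreement (ARI),
   per-gene metric deltas, and group comparisons of any metric between
   up- and down-regulated genes (Welch t-test by default; a documented
   1-df "compat" convention, `p = 2(½ − arctan|t|/π)`, reproduces older
   published tables).

Everything works offline: the `synth` module generates structurally
realistic inputs (distance-decaying intra-chromosomal contacts, planted
communities, controlled-rewiring pseudo-replicates with known expected
Jaccard `(1−f)/(1+f)` at rewiring fraction `f`).

## Worked example

```python
from hicnet.model import MultiExperimentGraph
from hicnet import analytics, compare

store = MultiExperimentGraph()
store.upsert_gene("AADACL3", "chr1", 12776118, 12788726)
store.upsert_gene("AADACL4", "chr1", 12704565, 12727097)
for name in ("T0_Rep1", "T_16_Rep1", "T_32_Rep1"):
    store.add_contact(name, "AADACL3", "AADACL4", weight=3, probability=0.8)

print(store.n_genes, store.n_contacts)
# 2 3        <- one gene pair, one edge per experiment; genes stored once

sub = store.experiment_subgraph("T0_Rep1")
print(sub.number_of_nodes(), sub.number_of_edges())
# 2 1

print(analytics.gene_neighbor_jaccard(store, "AADACL3", "T0_Rep1", "T_16_Rep1"))
# 1.0        <- identical neighbour sets in the two experiments
```

The two printed counts are the core of the data model: three experiments
contacting the same pair create three labelled edges but only two gene
nodes. A larger, fully synthetic session from the command line:

```sh
hicnet simulate --seed 1 --out sim/
hicnet ingest --contacts T0_Rep1=sim/T0_Rep1.tsv \
              --contacts T16_Rep1=sim/T16_Rep1.tsv \
              --genes sim/genes.bed --out store/
hicnet compare --store store/ --seed 1 --out cmp/
hicnet analyze --store store/ --experiment T0_Rep1 --metric louvain \
               --seed 7 --out out/
```

`cmp/jaccard_matrix.csv` holds the symmetric experiment-similarity matrix
(unit diagonal); `out/T0_Rep1_louvain.csv` maps each gene to its community.

Input formats: a tab-separated contact table
(`Gene1 Chr1 Start1 End1 Gene2 Chr2 Start2 End2 Weight Probability`, extra
columns become edge properties), BED gene annotation, optional binned
matrices (dense or coordinate triplets) converted to gene-pair edges, and
`gene,value` CSVs for overlays. Exports: a three-file TSV store, GraphML,
graph-database bulk-import CSVs and gene-list files for enrichment
services.

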