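# celltyper

Marker-based cell-type annotation for single-cell RNA-seq clusters, with
companion tools for QC filtering, gene-set enrichment, regulon
(motif-support) testing, cross-sample gene search and seeded synthetic
fixtures.

## Who this is for

Computational biologists who have a clustered scRNA-seq count matrix
(clusters from any upstream tool, e.g. Seurat) and a curated marker-gene
compendium, and want deterministic, per-cluster cell-type labels with a
significance estimate — plus the statistics a marker database needs
(gene frequency, marker weights, ubiquitousness, sensitivity).

## The method

Each cluster *k* is summarized by the per-gene **median** of normalized
expression (counts scaled per cell to a common depth, then log₂(x+1);
RPKM matrices use log₂(RPKM+1)). Against a marker compendium, every cell
type *j* with *N* markers receives a **cell-type activity (CTA) score**

```
S_jk = ( Σ_i  Z_ki · w_i ) / N^(1/3)
```

where `Z_ki` is the cluster's median expression of marker *i* (0 if the
gene is absent from the matrix) and

```
w(g) = 1 + sqrt( (max f − f(g)) / (max f − min f) )  ∈ [1, 2]
```

down-weights markers listed by many cell types (*f(g)* = number of cell
types listing gene *g*). Cell types are ranked by CTA; the winner's
significance is a one-sided Fisher (hypergeometric) test on the overlap of
the cluster's expressed genes (median > 0) with the marker set, BH-adjusted
across cell types. If the winner's adjusted p exceeds 0.05 the cluster is
labelled **Unknown**.

QC follows the standard order: cells with < 1000 reads are dropped, the top
5% of cells by doublet score are removed, clusters with < 10 cells are
discarded. Gene-set activity uses the same Fisher test over 10–500-gene
sets with Bonferroni α = 0.01; regulon support rescores motif hits (summing
per motif-gene pair), truncates rankings to the top 200 genes, computes
module recovery AUCs against the all-motif background, and integrates a
Gaussian KDE tail for significance (< 0.05).

## Worked example

```python
import celltyper as ct

cfg = ct.SimulationConfig(seed=42)           # 5 cell types x 20 markers,
table = ct.generate_marker_table(cfg)        # 8 clusters x 50 cells
matrix, clusters, truth = ct.generate_counts(cfg, table)
calls, _ = ct.run_pipeline(matrix, clusters, table)
for call in calls[:3]:
    w = call.winner
    print(call.cluster_id, call.label, round(w.cta, 2), f"{w.fdr:.3g}")
```

prints

```
0 CellType01 58.77 1.07e-67
1 CellType02 55.12 1.07e-67
2 CellType03 57.17 1.07e-67
```

— cluster 0 is called `CellType01` with CTA 58.77 (the weighted median
expression of its markers, cube-root-normalized) and an essentially zero
FDR: all 8 clusters recover their planted type. See `examples/` for one
narrative script per capability (annotation, marker statistics, gene-set
enrichment, regulons, gene search); each prints its results and a line on
what they mean. The same functionality is available from the shell via the
`celltyper` command (`simulate`, `qc`, `annotate`, `markers`, `gsa`,
`regulons`, `search`).

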