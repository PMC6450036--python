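# Methods

## Cluster profiles and normalization

Counts are depth-normalized per cell, `value = log2(count / depth × scale + 1)`
with `scale = 10000` by default (counts per 10k). No scale factor is
canonical for this transform; any positive scale preserves within-cell
ranks, the >0 "expressed" rule, and — because the CTA score is linear in
the profile — the identity of the winning cell type. RPKM matrices are
taken as already length-normalized and only receive `log2(x + 1)`.

A cluster is represented by the per-gene **median** over its cells'
normalized values (even-sized clusters take the midpoint of the two central
values). The median is robust to the zero-inflation of droplet data: a gene
is "expressed" in a cluster only when more than half its cells carry it.

## QC filters

Applied in the fixed order depth → doublets → cluster size, each
idempotent:

* cells need ≥ 1000 total reads (the depth filter runs first so later
  stages never see zero-depth cells);
* the top 5% of cells by doublet score are removed — `ceil(fraction · n)`
  cells, ties at the cut broken by barcode lexicographic order, because
  "top 5%" is otherwise ambiguous at ties and non-integer boundaries and
  determinism is a hard requirement here;
* clusters need ≥ 10 cells; cluster ids are never renumbered.

Doublet scores and cluster labels are inputs: doublet prediction and
clustering are upstream concerns.

## Marker weights and the CTA score

`f(g)` counts the **distinct cell types** listing gene `g`; records flagged
for both species are stored once so `f` is not inflated. The weight
`w(g) = 1 + sqrt((max f − f(g)) / (max f − min f))` is monotone
non-increasing in `f` and bounded in [1, 2]. When `max f = min f` the
formula is 0/0; with no frequency signal there is no basis for
down-weighting, so every gene keeps the maximally specific weight 2.

The CTA score `S = (Σ Z_i w_i) / N^(1/3)` uses the cluster median as `Z`
(the only cluster-level expression quantity the procedure constructs).
`N` is the full marker count of the cell type: markers absent from the
matrix contribute `Z = 0` but still enlarge the denominator, so a cell type
cannot profit from an unobservable marker list. The cube root is a
compromise between ignoring marker-list length entirely (favouring types
with huge lists) and averaging (over-penalizing them).

Winner selection ranks by CTA, breaking ties by smaller hypergeometric p
and then alphabetically — the tie rule is a determinism device, not a
scientific claim. Significance is the upper-tail hypergeometric probability
of the expressed/marker overlap with the matrix's gene axis as the
universe (the test needs a finite universe and the axis is the only one
available). BH runs across the cell types of one cluster, because the
Unknown rule is applied per cluster; the comparison with the 0.05 threshold
is strict (`fdr > 0.05` → Unknown, equality keeps the label).

## Marker statistics

The ubiquitousness index of a gene is the fraction of cluster profiles
with median > 0 — values near 1 flag housekeeping-like genes. Sensitivity
of a (marker, cell type) pair is defined here as the fraction of clusters
*called* as that type in which the marker is expressed. The verbal notion
of identifying a type "uniquely" admits other readings (e.g. penalizing
expression in clusters of other types); we use the expressed-fraction
reading and do not attempt a specificity correction.

## Gene-set activity

Enrichment of a cluster's expressed genes (same >0-median rule) in each
gene set, one-sided Fisher's exact test; sets are admitted when they have
10–500 genes *after* ortholog mapping (mapping changes effective sizes, so
the filter runs second); Bonferroni with α = 0.01, with n counted over the
tested (admissible) sets, since those are the hypotheses actually
evaluated. Ortholog maps must be one-to-one in both directions; genes
without a partner are dropped from every set.

## Regulons

Motif scanners emit many hits per motif-gene pair (clustered cis-regulatory
modules); hits are combined by summation, genes ranked per motif by the
combined score and truncated to the top 200 (ties lexicographic). For a
TF-centred co-expression module, the recovery curve
`R(t) = |members ∩ top-t| / |members|`, t = 1..200, gives an AUC (the mean
of R). The AUCs of the module against **all** motifs form the genomic
background; the significance of a TF-assigned motif is the upper-tail
integral of a Gaussian KDE (Silverman bandwidth, numeric integration via
the fitted density) over that background — chosen over a background
Z-score because AUC backgrounds are frequently non-Gaussian. The
significance threshold 0.05 applies to this tail integral. A background
needs ≥ 10 motifs; an all-identical background (no KDE bandwidth exists)
falls back to the empirical tail fraction.

A regulon's target set is the union over all supported motifs of the
module members present in the motif's top-200 ranking: if several motifs
of the same TF independently pass the background test, each contributes
the evidence it carries; restricting to the best motif would discard
support already deemed significant.

## Gene search

Search returns clusters where every required gene has median > 0 and every
excluded gene median 0. Ranks are competition ranks ("min" ties) computed
among expressed genes only — silent genes carry no rank, so rank 1 is
always the most highly expressed gene. Query symbols resolve through the
compendium's alias lists; ambiguous aliases (≥ 2 candidate symbols) are
rejected with the candidates listed.

## Synthetic data

The generator plants one cell type per cluster: planted-type markers draw
Poisson counts at `marker_mean` (default 5) then drop out per cell with
probability 0.3; all other genes draw Poisson at `background_mean`
(default 0.1). Per-cell means are rescaled so each cell's expected depth is
uniform in `library_depth_range` (default 1500–3000 reads, enough to clear
the 1000-read filter). The gene axis defaults to 20 000 background genes —
the scale of a mammalian annotation — which keeps the rescale factor near 1
so background genes stay genuinely silent (Poisson mean well below ln 2
means median 0 across a cluster); a much smaller axis would inflate
background means until every gene counted as expressed and the enrichment
test lost its contrast. A configurable fraction (default 0.1) of each
type's markers is shared with the adjacent type, exercising f(g) > 1 and
the down-weighting path. The default preset is 5 cell types × 20 markers,
8 clusters × 50 cells, seed 42.

The model is Poisson with Bernoulli dropout, not negative binomial:
overdispersion, ambient RNA, batch effects and doublet structure are
deliberately absent. Passing tests therefore demonstrate correctness of
the computations and recoverability of a clean planted signal, not
performance on real tissue data.

The motif fixture plants, per TF module, one motif whose hits rank the
module's 20 genes at the top (each pair split over two rows, exercising
hit summation) plus 180 filler genes; 47 decoy motifs hit 200 random genes
from a 1000-gene pool. Problem sizes throughout (400 cells, 50 motifs,
20k genes) are chosen so the full suite runs in seconds while keeping all
counting statistics away from small-sample degeneracies.

## Numerical and interface choices

* Hypergeometric tails via `scipy.stats.hypergeom.sf`, BH via
  `statsmodels`; tests check both against independent enumeration oracles.
* All TSV floats are serialized to 6 significant digits so reruns produce
  byte-identical artifacts.
* Composite gene identifiers (`symbol_ENSEMBLID`) split on the last
  underscore only when the suffix looks like an Ensembl accession, so
  symbols with internal underscores survive.
* Marker TSV alias lists are `|`-delimited (commas collide with the CLI's
  multi-gene syntax); unknown trailing columns round-trip unchanged.

## Known limitations

* Per-cluster annotation only: no per-cell calls, soft assignments or
  cell-type ontologies.
* Sensitivity/UI are descriptive statistics over one dataset's clusters,
  not calibrated probabilities.
* The regulon module consumes motif hit tables and co-expression modules;
  PWM scanning and network inference are out of scope.
* The continuous gene-set activity *score* of SCENIC-style pipelines is
  not implemented — only the enrichment test, admission rules and
  correction.
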