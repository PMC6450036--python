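"""Cell-type inference for cell clusters.

Each cluster is represented by the per-gene median of normalized expression.
For every candidate cell type j with N marker genes, a cell-type activity
(CTA) score is computed for cluster k:

    S_jk = ( sum_i Z_ki * w_i ) / N**(1/3)

where Z_ki is the cluster's median expression of marker i (zero when the
gene is absent from the matrix) and w_i the frequency-based marker weight.
Broad markers are down-weighted and the cube-root denominator adjusts for
the cell type's marker-list length.  Cell types are ranked by CTA; the top
type wins.  Significance is a one-sided Fisher (hypergeometric) test on the
overlap between the cluster's expressed genes (median > 0) and the marker
set, BH-adjusted across the cell types of the cluster; a winner whose
adjusted p exceeds 0.05 is reported as "Unknown".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .markers import GeneFrequency, MarkerTable, gene_frequency, marker_weight
from .qc import ClusterAssignment, NormalizedMatrix

__all__ = [
    "ClusterProfile",
    "CellTypeScore",
    "CellTypeCall",
    "UNKNOWN_LABEL",
    "cluster_medians",
    "cta_score",
    "cluster_p_value",
    "bh_adjust",
    "annotate_cluster",
    "annotate_sample",
]

UNKNOWN_LABEL = "Unknown"

#: A winner whose BH-adjusted p exceeds this is relabelled "Unknown".
DEFAULT_FDR_THRESHOLD = 0.05


@dataclass
class ClusterProfile:
    """Per-cluster vector of median normalized expression, one value per gene."""

    cluster_id: int
    n_cells: int
    median_expression: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("cluster must contain at least one cell")

    @property
    def expressed_genes(self) -> frozenset[str]:
        """Genes with median expression > 0."""
        return frozenset(g for g, v in self.median_expression.items() if v > 0.0)


@dataclass
class CellTypeScore:
    cell_type: str
    cta: float
    n_markers: int
    p_value: float
    fdr: float


@dataclass
class CellTypeCall:
    """Ranked cell-type scores for one cluster plus the final label."""

    cluster_id: int
    n_cells: int
    ranked_scores: list[CellTypeScore]
    label: str

    @property
    def winner(self) -> CellTypeScore:
        return self.ranked_scores[0]


def cluster_medians(
    m: NormalizedMatrix,
    assign: ClusterAssignment,
) -> list[ClusterProfile]:
    """Median normalized expression per gene, per cluster.

    Even-sized clusters take the mean of the two central values (the numpy
    median convention).  Barcodes in ``assign`` must exist in the matrix.
    """
    col = {b: i for i, b in enumerate(m.cells)}
    missing = [b for b in assign.assignments if b not in col]
    if missing:
        raise ValueError(f"assigned barcodes absent from matrix: {missing[:5]}")
    profiles: list[ClusterProfile] = []
    for cid in assign.cluster_ids:
        members = assign.members(cid)
        if not members:
            raise ValueError(f"cluster {cid} has no cells")
        idx = np.array(sorted(col[b] for b in members))
        dense = np.asarray(m.values[:, idx].todense())
        med = np.median(dense, axis=1)
        profiles.append(
            ClusterProfile(
                cluster_id=cid,
                n_cells=len(members),
                median_expression=dict(zip(m.genes, med.tolist())),
            )
        )
    return profiles


def cta_score(
    profile: ClusterProfile,
    cell_type: str,
    table: MarkerTable,
    freq: GeneFrequency,
) -> float:
    """Weighted cell-type activity score S = (sum Z_i w_i) / N**(1/3).

    N counts every marker listed for the cell type; markers absent from the
    matrix contribute Z = 0 but still enlarge the denominator, penalizing
    cell types whose marker lists are mostly unexpressed.
    """
    markers = table.markers_for(cell_type)
    n = len(markers)
    total = 0.0
    for g in markers:
        z = profile.median_expression.get(g, 0.0)
        if z:
            total += z * marker_weight(g, freq)
    return total / n ** (1.0 / 3.0)


def cluster_p_value(
    profile: ClusterProfile,
    cell_type: str,
    table: MarkerTable,
) -> float:
    """One-sided Fisher (hypergeometric) test on expressed vs marker genes.

    Universe = the matrix's gene axis; successes = the cell type's markers
    present in the universe; draws = the cluster's expressed genes
    (median > 0); observed = expressed markers.  Returns P(X >= k).
    """
    universe = set(profile.median_expression)
    if not universe:
        raise ValueError("empty gene universe")
    markers = table.markers_for(cell_type) & universe
    expressed = profile.expressed_genes
    k = len(expressed & markers)
    return float(hypergeom.sf(k - 1, len(universe), len(markers), len(expressed)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    Order-preserving with the input vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted.tolist()


def annotate_cluster(
    profile: ClusterProfile,
    table: MarkerTable,
    freq: Optional[GeneFrequency] = None,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> CellTypeCall:
    """Score every cell type for one cluster and pick the winner.

    CTA scores and hypergeometric p-values are computed for every cell type
    in the table; BH adjustment runs across the cell types of this cluster.
    Ties in CTA are broken by smaller p-value, then alphabetically.  The
    label is the top-ranked type when its adjusted p <= ``fdr_threshold``
    (equality keeps the label), else "Unknown".
    """
    if freq is None:
        freq = gene_frequency(table)
    cell_types = table.cell_types
    ctas = [cta_score(profile, ct, table, freq) for ct in cell_types]
    pvals = [cluster_p_value(profile, ct, table) for ct in cell_types]
    fdrs = bh_adjust(pvals)
    scores = [
        CellTypeScore(cell_type=ct, cta=s, n_markers=len(table.markers_for(ct)),
                      p_value=p, fdr=q)
        for ct, s, p, q in zip(cell_types, ctas, pvals, fdrs)
    ]
    scores.sort(key=lambda s: (-s.cta, s.p_value, s.cell_type))
    winner = scores[0]
    label = winner.cell_type if winner.fdr <= fdr_threshold else UNKNOWN_LABEL
    return CellTypeCall(
        cluster_id=profile.cluster_id,
        n_cells=profile.n_cells,
        ranked_scores=scores,
        label=label,
    )


def annotate_sample(
    m: NormalizedMatrix,
    assign: ClusterAssignment,
    table: MarkerTable,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[CellTypeCall]:
    """Annotate every cluster of a sample; deterministic given its inputs."""
    freq = gene_frequency(table)
    profiles = cluster_medians(m, assign)
    return [
        annotate_cluster(p, table, freq, fdr_threshold=fdr_threshold)
        for p in profiles
    ]
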