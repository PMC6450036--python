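"""Count-matrix containers, normalization and quality-control filters.

The pipeline order mirrors standard droplet scRNA-seq processing: cells with
fewer than 1000 deduplicated reads are dropped, the top 5% of cells by
doublet score are removed, clusters with fewer than 10 cells are discarded,
and the surviving counts are depth-normalized and log2(x+1) transformed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ClusterAssignment",
    "filter_cells_by_depth",
    "remove_doublets",
    "filter_clusters",
    "normalize_counts",
    "normalize_rpkm",
]


@dataclass
class CountMatrix:
    """Sparse genes × cells matrix of non-negative counts.

    ``assay`` distinguishes UMI/read counts (to be depth-normalized) from
    RPKM matrices that are already length-normalized upstream.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.spmatrix
    assay: str = "umi_counts"

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell barcodes must be unique")
        if self.assay not in ("umi_counts", "rpkm"):
            raise ValueError(f"unknown assay: {self.assay!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def depths(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in keep],
            counts=self.counts[:, keep],
            assay=self.assay,
        )


@dataclass
class NormalizedMatrix:
    """Genes × cells matrix of log2-transformed normalized expression.

    Zero raw counts stay exactly zero, so "expressed" (value > 0) is
    preserved by normalization.
    """

    genes: list[str]
    cells: list[str]
    values: sp.spmatrix

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("values shape does not match gene/cell axes")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("normalized values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class ClusterAssignment:
    """Map cell barcode → cluster id (0-indexed, Seurat-style labels)."""

    assignments: dict[str, int]

    def __post_init__(self) -> None:
        for barcode, cluster in self.assignments.items():
            if cluster < 0:
                raise ValueError(f"negative cluster id for {barcode!r}")

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def members(self, cluster_id: int) -> list[str]:
        return [b for b, c in self.assignments.items() if c == cluster_id]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return out

    def restrict_to(self, barcodes) -> "ClusterAssignment":
        """Keep only the given barcodes (e.g. after cell filtering)."""
        keep = set(barcodes)
        return ClusterAssignment(
            {b: c for b, c in self.assignments.items() if b in keep}
        )


def filter_cells_by_depth(m: CountMatrix, min_reads: int = 1000) -> CountMatrix:
    """Keep cells with at least ``min_reads`` total counts.

    The gene axis is unchanged.  Emits a warning (and returns an empty
    matrix) if every cell is removed.
    """
    keep = np.flatnonzero(m.depths() >= min_reads)
    if keep.size == 0:
        warnings.warn("depth filter removed every cell", stacklevel=2)
    return m.subset_cells(keep)


def remove_doublets(
    m: CountMatrix,
    scores: Mapping[str, float],
    fraction: float = 0.05,
) -> CountMatrix:
    """Remove the top ``fraction`` of cells by doublet score.

    Scores come from an upstream doublet predictor (e.g. Scrublet); this
    implements only the top-fraction cut.  ``ceil(fraction * n_cells)``
    cells are removed; ties at the cut are broken by barcode lexicographic
    order so the result is deterministic.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    missing = [b for b in m.cells if b not in scores]
    if missing:
        raise ValueError(f"missing doublet scores for barcodes: {missing}")
    n_remove = math.ceil(fraction * m.n_cells)
    if n_remove == 0:
        return m.subset_cells(np.arange(m.n_cells))
    order = sorted(range(m.n_cells), key=lambda i: (-scores[m.cells[i]], m.cells[i]))
    removed = set(order[:n_remove])
    keep = np.array([i for i in range(m.n_cells) if i not in removed])
    return m.subset_cells(keep)


def filter_clusters(assign: ClusterAssignment, min_cells: int = 10) -> ClusterAssignment:
    """Drop clusters with fewer than ``min_cells`` members; ids are kept as-is."""
    sizes = assign.sizes()
    keep = {c for c, n in sizes.items() if n >= min_cells}
    return ClusterAssignment(
        {b: c for b, c in assign.assignments.items() if c in keep}
    )


def normalize_counts(m: CountMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    """Depth-normalize counts and log2(x+1) transform.

    value(g, c) = log2(count(g, c) / depth(c) * scale + 1).  The scale
    factor (default 10 000, i.e. counts per 10k) keeps values in a
    log-friendly range; any positive scale preserves within-cell ranks.
    """
    if m.assay != "umi_counts":
        raise ValueError("normalize_counts expects a umi_counts matrix")
    if scale <= 0:
        raise ValueError("scale must be positive")
    depths = m.depths()
    if np.any(depths == 0):
        zero = [m.cells[i] for i in np.flatnonzero(depths == 0)]
        raise ValueError(
            f"cells with zero depth (apply the depth filter first): {zero}"
        )
    X = m.counts.astype(np.float64).tocsc(copy=True)
    X = X @ sp.diags(scale / depths)
    X = sp.csc_matrix(X)
    X.data = np.log2(X.data + 1.0)
    return NormalizedMatrix(genes=list(m.genes), cells=list(m.cells), values=X)


def normalize_rpkm(m: CountMatrix) -> NormalizedMatrix:
    """log2(RPKM + 1); the pseudo-count avoids log2(0) for silent genes."""
    if m.assay != "rpkm":
        raise ValueError("normalize_rpkm expects an rpkm matrix")
    X = m.counts.astype(np.float64).tocsc(copy=True)
    if X.nnz and X.data.min() < 0:
        raise ValueError("RPKM values must be non-negative")
    X.data = np.log2(X.data + 1.0)
    return NormalizedMatrix(genes=list(m.genes), cells=list(m.cells), values=X)
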