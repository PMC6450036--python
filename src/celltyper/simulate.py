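"""Seeded synthetic fixtures: marker tables, count matrices, motif tables.

The count generator emulates a droplet scRNA-seq sample with known cluster
structure: each cluster is planted with one cell type; markers of the
planted type draw counts from a Poisson at an elevated mean and are then
zeroed per cell with a dropout probability, all other genes draw from a low
background Poisson, and per-cell means are rescaled so total depth lands
uniformly inside a target library-size window.  It deliberately omits
overdispersion, ambient RNA and batch effects — it exercises the >0
expression rule and median statistics, not realistic noise.

All generators are pure functions of their configuration (including the
seed): same config, byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .markers import MarkerRecord, MarkerTable
from .qc import ClusterAssignment, CountMatrix
from .regulons import CoexpressionModule, MotifHitTable

__all__ = ["SimulationConfig", "generate_marker_table", "generate_counts",
           "generate_motif_fixture", "marker_table_with_frequencies"]

_GERM_LAYERS = ("Ectoderm", "Mesoderm", "Endoderm")
_ORGANS = ("Brain", "Heart", "Liver", "Lung", "Kidney", "Pancreas")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    ``marker_mean`` and ``background_mean`` are expected counts per cell
    before library-depth rescaling; the actual per-cell depth is drawn
    uniformly from ``library_depth_range`` (reads per cell), chosen so a
    default fixture passes a 1000-read cell filter.  The default gene axis
    (20 000 background genes, the scale of a mammalian annotation) makes the
    expected raw depth close to the target window, so the rescaling factor
    stays near 1 and the configured means are honoured — in particular
    background genes stay mostly silent (Poisson mean well below ln 2, hence
    median 0), which is what makes the >0 expression rule informative.  ``shared_marker_fraction`` of each cell type's markers are
    shared with the adjacent type, exercising gene frequencies above 1 and
    the down-weighting path.
    """

    n_cell_types: int = 5
    markers_per_type: int = 20
    n_clusters: int = 8
    cells_per_cluster: int = 50
    n_background_genes: int = 20000
    marker_mean: float = 5.0
    background_mean: float = 0.1
    dropout_prob: float = 0.3
    shared_marker_fraction: float = 0.1
    library_depth_range: tuple[int, int] = (1500, 3000)
    seed: int = 42
    # motif fixture dimensions
    n_motifs: int = 50
    n_modules: int = 3
    module_size: int = 20
    motif_gene_pool: int = 1000

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "markers_per_type", "n_clusters",
                     "cells_per_cluster", "n_background_genes", "n_motifs",
                     "n_modules", "module_size", "motif_gene_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must lie in [0, 1]")
        if not (0.0 <= self.shared_marker_fraction <= 1.0):
            raise ValueError("shared_marker_fraction must lie in [0, 1]")
        lo, hi = self.library_depth_range
        if lo < 1 or hi < lo:
            raise ValueError("library_depth_range must be a positive (lo, hi) pair")


def marker_table_with_frequencies(freqs: dict[str, int]) -> MarkerTable:
    """Build a table in which gene g is listed by exactly ``freqs[g]`` cell types.

    Gene g is assigned to cell types CT01..CT{f(g)}, so the realized
    f(g) equals the prescribed value and the frequency range spans
    min(freqs) .. max(freqs).  Useful for exercising the weight formula at
    chosen boundary values.
    """
    if not freqs or any(f < 1 for f in freqs.values()):
        raise ValueError("frequencies must be positive integers")
    records = [
        MarkerRecord(species="Mm", gene_symbol=gene, cell_type=f"CT{t + 1:02d}")
        for gene, f in sorted(freqs.items())
        for t in range(f)
    ]
    return MarkerTable(records)


def generate_marker_table(cfg: SimulationConfig) -> MarkerTable:
    """Build a marker compendium with planted cell types.

    Cell type t shares ``round(shared_marker_fraction * markers_per_type)``
    markers with cell type t+1 (its first markers are the previous type's
    last), so some genes have frequency 2.
    """
    n_shared = round(cfg.shared_marker_fraction * cfg.markers_per_type)
    records: list[MarkerRecord] = []
    counter = 0
    prev_markers: list[str] = []
    for t in range(cfg.n_cell_types):
        cell_type = f"CellType{t + 1:02d}"
        markers: list[str] = []
        if t > 0 and n_shared > 0:
            markers.extend(prev_markers[-n_shared:])
        while len(markers) < cfg.markers_per_type:
            counter += 1
            markers.append(f"M{counter:04d}")
        for j, gene in enumerate(markers):
            records.append(
                MarkerRecord(
                    species="Mm",
                    gene_symbol=gene,
                    cell_type=cell_type,
                    aliases=(f"{gene}-alias",),
                    germ_layer=_GERM_LAYERS[t % len(_GERM_LAYERS)],
                    organ=_ORGANS[t % len(_ORGANS)],
                    canonical=(j == 0),
                )
            )
        prev_markers = markers
    return MarkerTable(records)


def generate_counts(
    cfg: SimulationConfig,
    table: MarkerTable,
) -> tuple[CountMatrix, ClusterAssignment, dict[int, str]]:
    """Simulate a clustered count matrix with planted cell types.

    Returns the sparse count matrix, the per-cell cluster assignment and
    the planted truth (cluster id → cell type).  Cluster k is planted with
    cell type ``k mod n_cell_types``.
    """
    rng = np.random.default_rng(cfg.seed)
    cell_types = table.cell_types
    genes = sorted(table.genes) + [
        f"B{i + 1:04d}" for i in range(cfg.n_background_genes)
    ]
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    barcodes: list[str] = []
    assignments: dict[str, int] = {}
    truth: dict[int, str] = {}
    columns: list[np.ndarray] = []
    lo, hi = cfg.library_depth_range
    for k in range(cfg.n_clusters):
        planted = cell_types[k % len(cell_types)]
        truth[k] = planted
        marker_rows = np.array(
            sorted(gene_idx[g] for g in table.markers_for(planted))
        )
        base = np.full(n_genes, cfg.background_mean)
        base[marker_rows] = cfg.marker_mean
        # expected depth before rescale, accounting for marker dropout
        expected = (
            cfg.marker_mean * (1.0 - cfg.dropout_prob) * marker_rows.size
            + cfg.background_mean * (n_genes - marker_rows.size)
        )
        for j in range(cfg.cells_per_cluster):
            barcode = f"C{k:02d}_{j:03d}"
            barcodes.append(barcode)
            assignments[barcode] = k
            target_depth = rng.integers(lo, hi + 1)
            counts = rng.poisson(base * (target_depth / expected))
            dropped = rng.random(marker_rows.size) < cfg.dropout_prob
            counts[marker_rows[dropped]] = 0
            columns.append(counts)
    matrix = sp.csc_matrix(
        np.column_stack(columns), dtype=np.int64
    )
    cm = CountMatrix(genes=genes, cells=barcodes, counts=matrix,
                     assay="umi_counts")
    return cm, ClusterAssignment(assignments), truth


def generate_motif_fixture(
    cfg: SimulationConfig,
) -> tuple[MotifHitTable, list[CoexpressionModule], dict[str, str], dict[str, str]]:
    """Motif hit table with planted TF-motif support.

    Each of ``n_modules`` transcription factors gets a module of
    ``module_size`` genes drawn from a shared pool, and one planted motif
    whose hits put the module genes at the top of its ranking (each pair
    split over two rows so score summation is exercised).  The remaining
    motifs are decoys hitting random genes with random scores.

    Returns (hits, modules, motif → TF map, planted TF → motif map).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pool = [f"G{i + 1:04d}" for i in range(cfg.motif_gene_pool)]
    modules: list[CoexpressionModule] = []
    rows: list[tuple[str, str, float]] = []
    motif_tf_map: dict[str, str] = {}
    planted: dict[str, str] = {}
    for m in range(cfg.n_modules):
        tf = f"TF{m + 1}"
        members = rng.choice(pool, size=cfg.module_size, replace=False)
        modules.append(CoexpressionModule(tf=tf, members=frozenset(members)))
        motif = f"MOTIF_{tf}"
        motif_tf_map[motif] = tf
        planted[tf] = motif
        for gene in members:
            score = rng.uniform(90.0, 100.0)
            rows.append((motif, gene, score / 2))
            rows.append((motif, gene, score / 2))
        fillers = rng.choice(
            [g for g in pool if g not in set(members)], size=180, replace=False
        )
        for gene in fillers:
            rows.append((motif, gene, float(rng.uniform(1.0, 50.0))))
    n_decoys = cfg.n_motifs - cfg.n_modules
    for d in range(n_decoys):
        motif = f"DECOY_{d + 1:03d}"
        hit_genes = rng.choice(pool, size=200, replace=False)
        for gene in hit_genes:
            rows.append((motif, gene, float(rng.uniform(1.0, 100.0))))
    return MotifHitTable(rows), modules, motif_tf_map, planted
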