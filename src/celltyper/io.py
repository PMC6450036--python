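"""Readers and writers for the on-disk formats the toolkit consumes.

Count matrices travel as MatrixMarket coordinate files with ``genes.tsv``
and ``barcodes.tsv`` sidecars (the 10x/CellRanger layout) or as dense CSV
with genes as rows.  Gene identifiers may be composite ``symbol_ENSEMBLID``
strings, split on the last underscore.  Cluster assignments, doublet
scores, motif hits, co-expression modules and motif→TF maps are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .inference import CellTypeCall
from .qc import ClusterAssignment, CountMatrix
from .regulons import CoexpressionModule, MotifHitTable, Regulon

__all__ = [
    "split_gene_id",
    "read_matrix_dir",
    "write_matrix_dir",
    "read_dense_csv",
    "read_cluster_tsv",
    "write_cluster_tsv",
    "read_doublet_scores",
    "read_motif_hits",
    "read_modules",
    "read_motif_tf_map",
    "write_annotations",
    "write_regulons",
    "fmt_float",
]


def fmt_float(x: float) -> str:
    """Fixed 6-significant-digit float formatting for reproducible diffs."""
    return f"{x:.6g}"


def split_gene_id(identifier: str) -> tuple[str, Optional[str]]:
    """Split a composite ``symbol_ENSEMBLID`` gene identifier.

    The split is on the *last* underscore and only when the suffix looks
    like an Ensembl accession; bare symbols pass through with ``None``.
    """
    if "_" in identifier:
        symbol, suffix = identifier.rsplit("_", 1)
        if suffix.startswith("ENS") and suffix[3:].lstrip("MUSGT").isdigit():
            return symbol, suffix
    return identifier, None


def read_matrix_dir(path: str | Path, assay: str = "umi_counts") -> CountMatrix:
    """Read matrix.mtx + genes.tsv + barcodes.tsv from a directory."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    counts = sp.csc_matrix(scipy.io.mmread(mtx))
    genes = [
        line.split("\t")[0]
        for line in (path / "genes.tsv").read_text().splitlines()
        if line.strip()
    ]
    barcodes = [
        line.strip()
        for line in (path / "barcodes.tsv").read_text().splitlines()
        if line.strip()
    ]
    return CountMatrix(genes=genes, cells=barcodes, counts=counts, assay=assay)


def write_matrix_dir(m: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts))
    (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.genes))
    (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.cells))


def read_dense_csv(path: str | Path, assay: str = "umi_counts") -> CountMatrix:
    """Dense CSV with genes as rows, barcodes as column header."""
    df = pd.read_csv(path, index_col=0)
    counts = sp.csc_matrix(df.to_numpy())
    return CountMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        counts=counts,
        assay=assay,
    )


def read_cluster_tsv(path: str | Path) -> ClusterAssignment:
    """Two columns (barcode, cluster id), no header."""
    assignments: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        barcode, cluster = line.split("\t")[:2]
        assignments[barcode] = int(cluster)
    return ClusterAssignment(assignments)


def write_cluster_tsv(assign: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for barcode in sorted(assign.assignments):
            fh.write(f"{barcode}\t{assign.assignments[barcode]}\n")


def read_doublet_scores(path: str | Path) -> dict[str, float]:
    """Two columns (barcode, score), no header."""
    scores: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        barcode, score = line.split("\t")[:2]
        scores[barcode] = float(score)
    return scores


def read_motif_hits(
    path: str | Path,
    motif_col: int = 0,
    gene_col: int = 1,
    score_col: int = 2,
) -> MotifHitTable:
    """Motif hit TSV (motif, gene, score); header optional.

    Column indices are configurable so fimo's ``--text`` layout (motif in
    column 0, gene in column 2, score in column 6) can be consumed directly.
    """
    rows: list[tuple[str, str, float]] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            score = float(fields[score_col])
        except ValueError:
            if i == 0:  # header row
                continue
            raise
        rows.append((fields[motif_col], fields[gene_col], score))
    return MotifHitTable(rows)


def write_motif_hits(table: MotifHitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tgene\tscore\n")
        for motif, gene, score in table.rows:
            fh.write(f"{motif}\t{gene}\t{fmt_float(score)}\n")


def read_modules(path: str | Path) -> list[CoexpressionModule]:
    """Module TSV: one (tf, member gene) pair per row; header optional."""
    members: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        tf, gene = line.rstrip("\n").split("\t")[:2]
        if i == 0 and tf.lower() in ("tf", "transcription_factor"):
            continue
        members.setdefault(tf, set()).add(gene)
    return [
        CoexpressionModule(tf=tf, members=frozenset(genes))
        for tf, genes in sorted(members.items())
    ]


def write_modules(modules, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tmember\n")
        for module in modules:
            for gene in sorted(module.members):
                fh.write(f"{module.tf}\t{gene}\n")


def read_motif_tf_map(path: str | Path) -> dict[str, str]:
    """Motif→TF TSV: motif_id, tf; header optional."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        motif, tf = line.rstrip("\n").split("\t")[:2]
        if i == 0 and motif.lower() in ("motif", "motif_id"):
            continue
        out[motif] = tf
    return out


def write_motif_tf_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\ttf\n")
        for motif in sorted(mapping):
            fh.write(f"{motif}\t{mapping[motif]}\n")


def write_annotations(
    calls: list[CellTypeCall],
    path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Annotation TSV: one row per cluster, plus the top-5 runner-up types.

    With ``json_path`` the full ranked score list per cluster is also
    written as JSON.
    """
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tn_cells\tlabel\tcta_score\tp_value\tfdr\ttop_5_alternatives\n"
        )
        for call in calls:
            winner = call.winner
            alts = ";".join(
                f"{s.cell_type}:{fmt_float(s.cta)}"
                for s in call.ranked_scores[1:6]
            )
            fh.write(
                f"{call.cluster_id}\t{call.n_cells}\t{call.label}\t"
                f"{fmt_float(winner.cta)}\t{fmt_float(winner.p_value)}\t"
                f"{fmt_float(winner.fdr)}\t{alts}\n"
            )
    if json_path is not None:
        payload = [
            {
                "cluster_id": call.cluster_id,
                "n_cells": call.n_cells,
                "label": call.label,
                "scores": [
                    {
                        "cell_type": s.cell_type,
                        "cta": float(fmt_float(s.cta)),
                        "n_markers": s.n_markers,
                        "p_value": float(fmt_float(s.p_value)),
                        "fdr": float(fmt_float(s.fdr)),
                    }
                    for s in call.ranked_scores
                ],
            }
            for call in calls
        ]
        Path(json_path).write_text(json.dumps(payload, indent=1) + "\n")


def write_regulons(regulons: list[Regulon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tmotif\tauc\tsignificance\tn_targets\ttargets\n")
        for reg in regulons:
            targets = ";".join(sorted(reg.targets))
            for motif, auc, sig in reg.supported_motifs:
                fh.write(
                    f"{reg.tf}\t{motif}\t{fmt_float(auc)}\t{fmt_float(sig)}\t"
                    f"{len(reg.targets)}\t{targets}\n"
                )
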