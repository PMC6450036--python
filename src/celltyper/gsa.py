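"""Gene-set activity enrichment per cluster.

Gene sets (e.g. MSigDB signatures read from GMT) are tested for enrichment
in a cluster's expressed genes (median > 0, the same rule used for cell-type
inference) with a one-sided Fisher's exact test.  Only sets with 10-500
genes are tested; Bonferroni correction at alpha = 0.01 controls multiple
testing.  For mouse samples the analysis can be restricted to one-to-one
human-mouse orthologs via a user-supplied map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "OrthologMap",
    "read_gmt",
    "read_ortholog_map",
    "filter_gene_sets",
    "map_orthologs",
    "gsa_test",
    "bonferroni_select",
    "cluster_gene_set_activity",
]

DEFAULT_MIN_SIZE = 10
DEFAULT_MAX_SIZE = 500
DEFAULT_ALPHA = 0.01


@dataclass
class GeneSetCollection:
    """Named gene sets; genes within each set are unique."""

    sets: dict[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                self.sets[name] = tuple(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class OrthologMap:
    """One-to-one gene map (e.g. mouse symbol → human symbol)."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        values = list(self.pairs.values())
        if len(set(values)) != len(values):
            dup = sorted({v for v in values if values.count(v) > 1})
            raise ValueError(f"ortholog map is not one-to-one; duplicated targets: {dup[:5]}")


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated genes."""
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line[:60]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            sets[name] = tuple(dict.fromkeys(g for g in fields[2:] if g))
    return GeneSetCollection(sets=sets, source=source or str(path))


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Two-column TSV (source gene, target gene), no header required."""
    pairs: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            src, dst = line.rstrip("\n").split("\t")[:2]
            if src in ("source", "mouse", "gene"):  # tolerate a header row
                continue
            if src in pairs:
                raise ValueError(f"gene mapped twice: {src!r}")
            pairs[src] = dst
    return OrthologMap(pairs)


def filter_gene_sets(
    collection: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> GeneSetCollection:
    """Keep sets with min_size <= |set| <= max_size (both ends inclusive)."""
    kept = {
        name: genes
        for name, genes in collection.sets.items()
        if min_size <= len(genes) <= max_size
    }
    return GeneSetCollection(sets=kept, source=collection.source)


def map_orthologs(
    collection: GeneSetCollection,
    ortho: OrthologMap,
) -> GeneSetCollection:
    """Translate every set through a one-to-one ortholog map.

    Genes without a one-to-one partner are dropped.  Apply before size
    filtering, since mapping changes effective set sizes.
    """
    mapped = {
        name: tuple(dict.fromkeys(ortho.pairs[g] for g in genes if g in ortho.pairs))
        for name, genes in collection.sets.items()
    }
    return GeneSetCollection(sets=mapped, source=collection.source)


def gsa_test(
    expressed: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-sided Fisher (hypergeometric) enrichment p-value.

    Upper-tail probability of the observed overlap between the expressed
    genes and the gene set, both intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_set = set(gene_set) & universe
    expressed = set(expressed) & universe
    k = len(expressed & gene_set)
    return float(
        hypergeom.sf(k - 1, len(universe), len(gene_set), len(expressed))
    )


def bonferroni_select(
    p_values: Mapping[str, float],
    alpha: float = DEFAULT_ALPHA,
) -> set[str]:
    """Names with p <= alpha / n_tested (n = number of tested sets)."""
    n = len(p_values)
    if n == 0:
        return set()
    for name, p in p_values.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1] for {name!r}: {p}")
    threshold = alpha / n
    return {name for name, p in p_values.items() if p <= threshold}


def cluster_gene_set_activity(
    profile,
    collection: GeneSetCollection,
    ortho: OrthologMap | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    alpha: float = DEFAULT_ALPHA,
) -> list[dict]:
    """Run the full per-cluster enrichment: map, filter, test, correct.

    Returns one row per tested set: name, overlap, set size (within the
    universe), p and significance after Bonferroni.
    """
    if ortho is not None:
        collection = map_orthologs(collection, ortho)
    collection = filter_gene_sets(collection, min_size=min_size, max_size=max_size)
    universe = set(profile.median_expression)
    expressed = profile.expressed_genes
    pvals = {
        name: gsa_test(expressed, genes, universe)
        for name, genes in collection.sets.items()
    }
    selected = bonferroni_select(pvals, alpha=alpha)
    rows = []
    for name, genes in sorted(collection.sets.items()):
        in_universe = set(genes) & universe
        rows.append(
            {
                "cluster_id": profile.cluster_id,
                "set_name": name,
                "overlap": len(expressed & in_universe),
                "set_size": len(in_universe),
                "p": pvals[name],
                "significant": name in selected,
            }
        )
    return rows
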