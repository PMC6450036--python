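"""Gene search across annotated cluster profiles.

Mirrors a database search over many samples: each result row is one cell
cluster in which every required gene has median expression above zero and
every excluded gene is silent.  Within a cluster, expression is reported as
a competition rank (the most highly expressed gene has rank 1; ties share
the minimum rank; silent genes have no rank), making levels comparable
across datasets with different depths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .inference import ClusterProfile

__all__ = [
    "ClusterIndexRow",
    "ClusterIndex",
    "SearchRow",
    "expression_rank",
    "resolve_symbol",
    "search",
    "summarize_by_cell_type",
]


@dataclass
class ClusterIndexRow:
    sample_id: str
    cluster_id: int
    tissue: str
    label: str
    profile: ClusterProfile
    species: str = "Mm"


@dataclass
class ClusterIndex:
    """Searchable collection of cluster profiles across samples."""

    rows: list[ClusterIndexRow]

    def __post_init__(self) -> None:
        keys = [(r.sample_id, r.cluster_id) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("(sample_id, cluster_id) pairs must be unique")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SearchRow:
    species: str
    sample_id: str
    cluster_id: int
    tissue: str
    label: str
    ranks: dict[str, int]


def expression_rank(profile: ClusterProfile, gene: str) -> Optional[int]:
    """Competition rank of ``gene`` among the cluster's expressed genes.

    Rank 1 is the most highly expressed gene; tied medians share the minimum
    rank.  Genes with median 0 are unranked (``None``).  A gene off the
    profile's axis is a lookup error.
    """
    if gene not in profile.median_expression:
        raise KeyError(f"gene not on the profile's axis: {gene!r}")
    value = profile.median_expression[gene]
    if value <= 0.0:
        return None
    higher = sum(1 for v in profile.median_expression.values() if v > value)
    return higher + 1


def resolve_symbol(symbol: str, alias_map: dict[str, set[str]]) -> str:
    """Resolve a queried symbol through an alias map.

    Unambiguous aliases map to their official symbol; an alias pointing to
    two or more symbols is rejected with the candidates listed.  Unknown
    symbols pass through unchanged (they may simply be official symbols).
    """
    targets = alias_map.get(symbol)
    if targets is None:
        return symbol
    if len(targets) > 1:
        raise ValueError(
            f"ambiguous alias {symbol!r}: candidates {sorted(targets)}"
        )
    return next(iter(targets))


def search(
    index: ClusterIndex,
    require: Sequence[str] = (),
    exclude: Sequence[str] = (),
) -> list[SearchRow]:
    """Boolean AND/NOT search over cluster profiles.

    Returns clusters where every ``require`` gene has median > 0 and every
    ``exclude`` gene has median 0 (absent genes count as silent).  Rows
    carry the expression ranks of the required genes.
    """
    overlap = set(require) & set(exclude)
    if overlap:
        raise ValueError(f"genes both required and excluded: {sorted(overlap)}")
    out: list[SearchRow] = []
    for row in index.rows:
        med = row.profile.median_expression
        if any(med.get(g, 0.0) <= 0.0 for g in require):
            continue
        if any(med.get(g, 0.0) > 0.0 for g in exclude):
            continue
        ranks = {g: expression_rank(row.profile, g) for g in require}
        out.append(
            SearchRow(
                species=row.species,
                sample_id=row.sample_id,
                cluster_id=row.cluster_id,
                tissue=row.tissue,
                label=row.label,
                ranks={g: r for g, r in ranks.items() if r is not None},
            )
        )
    return out


def summarize_by_cell_type(rows: Sequence[SearchRow]) -> dict[str, int]:
    """Count result clusters per inferred cell-type label."""
    return dict(Counter(r.label for r in rows))
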