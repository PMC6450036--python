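"""Curated marker-gene compendium: data model, TSV I/O and marker statistics.

The compendium associates genes with cell types (per species, organ and germ
layer).  From it we derive the gene frequency f(g) — the number of cell types
listing gene g as a marker — and the down-weighting function

    w(g) = 1 + sqrt((max f - f(g)) / (max f - min f)),

bounded in [1, 2]: genes shared by many cell types approach weight 1, genes
specific to a single cell type get weight 2.  Two descriptive statistics are
computed against annotated cluster profiles: the ubiquitousness index (UI, the
fraction of clusters in which a gene is expressed) and per-marker sensitivity
(the fraction of clusters called as the marker's cell type in which the marker
is expressed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "MarkerRecord",
    "MarkerTable",
    "GeneFrequency",
    "MarkerFormatError",
    "read_marker_table",
    "write_marker_table",
    "gene_frequency",
    "marker_weight",
    "ubiquitousness_index",
    "marker_sensitivity",
]

SPECIES = ("Mm", "Hs", "both")

#: Column order of the marker TSV dialect.  ``canonical`` is an optional
#: trailing column; further unknown columns are preserved on round-trip.
MARKER_COLUMNS = (
    "species",
    "gene_symbol",
    "ui",
    "sensitivity",
    "marker_count",
    "cell_type",
    "germ_layer",
    "organ",
    "aliases",
    "product_description",
    "disease",
)

MANDATORY_COLUMNS = ("species", "gene_symbol", "cell_type")

ALIAS_DELIMITER = "|"


class MarkerFormatError(ValueError):
    """Raised for malformed marker tables (missing columns, duplicates...)."""


@dataclass(frozen=True)
class MarkerRecord:
    """One gene → cell-type association.

    ``species`` is ``Mm``, ``Hs`` or ``both`` (a record flagged ``both`` is
    stored once, not duplicated per species, so that f(g) is not inflated).
    ``ui`` and ``sensitivity`` are optional fractions in [0, 1].
    """

    species: str
    gene_symbol: str
    cell_type: str
    aliases: tuple[str, ...] = ()
    germ_layer: str = ""
    organ: str = ""
    canonical: bool = False
    ui: Optional[float] = None
    sensitivity: Optional[float] = None
    product_description: str = ""
    disease_flag: bool = False
    extras: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise MarkerFormatError(
                f"species must be one of {SPECIES}, got {self.species!r}"
            )
        if not self.gene_symbol:
            raise MarkerFormatError("gene_symbol must be non-empty")
        if not self.cell_type:
            raise MarkerFormatError("cell_type must be non-empty")
        for name, value in (("ui", self.ui), ("sensitivity", self.sensitivity)):
            if value is not None and not (0.0 <= value <= 1.0):
                raise MarkerFormatError(f"{name} must lie in [0, 1], got {value}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species, self.gene_symbol, self.cell_type)


@dataclass
class MarkerTable:
    """A collection of :class:`MarkerRecord` with a cell-type → gene index.

    A gene may map to more than one cell type; (species, gene, cell type)
    triples are unique and every cell type has at least one marker by
    construction.
    """

    records: list[MarkerRecord]
    _by_cell_type: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        index: dict[str, set[str]] = {}
        for rec in self.records:
            if rec.key in seen:
                raise MarkerFormatError(
                    f"duplicate (species, gene, cell_type) record: {rec.key}"
                )
            seen.add(rec.key)
            index.setdefault(rec.cell_type, set()).add(rec.gene_symbol)
        self._by_cell_type = {ct: frozenset(g) for ct, g in index.items()}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self._by_cell_type)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene_symbol for r in self.records)

    def markers_for(self, cell_type: str) -> frozenset[str]:
        try:
            return self._by_cell_type[cell_type]
        except KeyError:
            raise KeyError(f"unknown cell type: {cell_type!r}") from None

    def alias_map(self) -> dict[str, set[str]]:
        """Map alias → set of official symbols it could stand for."""
        amap: dict[str, set[str]] = {}
        for rec in self.records:
            for alias in rec.aliases:
                amap.setdefault(alias, set()).add(rec.gene_symbol)
        return amap


@dataclass(frozen=True)
class GeneFrequency:
    """f(g): number of distinct cell types listing gene g, with its extrema."""

    f: Mapping[str, int]
    f_min: int
    f_max: int

    def __post_init__(self) -> None:
        if self.f_min < 1:
            raise ValueError("f_min must be >= 1")

    def __contains__(self, gene: str) -> bool:
        return gene in self.f

    def __getitem__(self, gene: str) -> int:
        try:
            return self.f[gene]
        except KeyError:
            raise KeyError(f"gene not present in frequency table: {gene!r}") from None


def _parse_optional_fraction(value: object, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text in ("", "NA", "nan"):
        return None
    try:
        out = float(text)
    except ValueError:
        raise MarkerFormatError(
            f"row {row}: column {column!r} is not a number: {text!r}"
        ) from None
    return out


def read_marker_table(
    path: str | Path,
    species_filter: Optional[str] = None,
) -> MarkerTable:
    """Read a marker compendium TSV.

    Parameters
    ----------
    path
        Tab-separated file with a header row; mandatory columns are
        ``species``, ``gene_symbol`` and ``cell_type`` (the full dialect in
        :data:`MARKER_COLUMNS`).  Alias lists are ``|``-delimited.
    species_filter
        ``"Mm"`` or ``"Hs"``; records flagged ``both`` always match.
        ``None`` keeps everything.

    Raises
    ------
    MarkerFormatError
        On a missing mandatory column, duplicate (species, gene, cell type)
        triple, or an empty table after filtering.
    """
    if species_filter is not None and species_filter not in ("Mm", "Hs"):
        raise ValueError(f"species_filter must be 'Mm' or 'Hs', got {species_filter!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MarkerFormatError(f"missing mandatory column: {col!r}")
    known = set(MARKER_COLUMNS) | {"canonical"}
    extra_cols = [c for c in df.columns if c not in known]

    records: list[MarkerRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        species = row_d["species"].strip()
        if species_filter is not None and species not in (species_filter, "both"):
            continue
        aliases = tuple(
            a.strip()
            for a in row_d.get("aliases", "").split(ALIAS_DELIMITER)
            if a.strip()
        )
        records.append(
            MarkerRecord(
                species=species,
                gene_symbol=row_d["gene_symbol"].strip(),
                cell_type=row_d["cell_type"].strip(),
                aliases=aliases,
                germ_layer=row_d.get("germ_layer", "").strip(),
                organ=row_d.get("organ", "").strip(),
                canonical=row_d.get("canonical", "").strip().lower()
                in ("1", "true", "y", "yes"),
                ui=_parse_optional_fraction(row_d.get("ui"), "ui", i),
                sensitivity=_parse_optional_fraction(
                    row_d.get("sensitivity"), "sensitivity", i
                ),
                product_description=row_d.get("product_description", ""),
                disease_flag=row_d.get("disease", "").strip() == "Y",
                extras=tuple((c, row_d[c]) for c in extra_cols),
            )
        )
    if not records:
        raise MarkerFormatError("empty table (no records after species filtering)")
    return MarkerTable(records)


def write_marker_table(table: MarkerTable, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_marker_table` (round-trip safe)."""
    extra_cols: list[str] = []
    for rec in table.records:
        for col, _ in rec.extras:
            if col not in extra_cols:
                extra_cols.append(col)
    rows = []
    for rec in table.records:
        row = {
            "species": rec.species,
            "gene_symbol": rec.gene_symbol,
            "ui": "" if rec.ui is None else f"{rec.ui:.6g}",
            "sensitivity": "" if rec.sensitivity is None else f"{rec.sensitivity:.6g}",
            "marker_count": "",
            "cell_type": rec.cell_type,
            "germ_layer": rec.germ_layer,
            "organ": rec.organ,
            "aliases": ALIAS_DELIMITER.join(rec.aliases),
            "product_description": rec.product_description,
            "disease": "Y" if rec.disease_flag else "",
            "canonical": "Y" if rec.canonical else "",
        }
        row.update(dict(rec.extras))
        rows.append(row)
    columns = list(MARKER_COLUMNS) + ["canonical"] + extra_cols
    freq = gene_frequency(table)
    for row in rows:
        row["marker_count"] = str(freq[row["gene_symbol"]])
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def gene_frequency(table: MarkerTable) -> GeneFrequency:
    """Count, per gene, the number of distinct cell types listing it."""
    if not table.records:
        raise ValueError("marker table is empty")
    counts: dict[str, set[str]] = {}
    for rec in table.records:
        counts.setdefault(rec.gene_symbol, set()).add(rec.cell_type)
    f = {g: len(cts) for g, cts in counts.items()}
    return GeneFrequency(f=f, f_min=min(f.values()), f_max=max(f.values()))


def marker_weight(gene: str, freq: GeneFrequency) -> float:
    """Down-weighting w(g) = 1 + sqrt((max f - f(g)) / (max f - min f)).

    Bounded in [1, 2].  When every gene has the same frequency the ratio is
    0/0; with no frequency signal no down-weighting is warranted, so all
    genes keep the maximally specific weight 2.
    """
    f_g = freq[gene]
    if freq.f_max == freq.f_min:
        return 2.0
    return 1.0 + math.sqrt((freq.f_max - f_g) / (freq.f_max - freq.f_min))


def ubiquitousness_index(gene: str, profiles: Sequence) -> float:
    """Fraction of cluster profiles in which ``gene`` has median expression > 0.

    Values toward 1 indicate expression in most clusters (housekeeping-like
    behaviour).  A gene absent from every profile has UI 0.
    """
    if not profiles:
        raise ValueError("at least one cluster profile is required")
    n_expressed = sum(
        1 for p in profiles if p.median_expression.get(gene, 0.0) > 0.0
    )
    return n_expressed / len(profiles)


def marker_sensitivity(
    gene: str,
    cell_type: str,
    calls: Sequence,
    profiles: Sequence,
) -> Optional[float]:
    """Fraction of clusters labelled ``cell_type`` in which ``gene`` is expressed.

    Measures how often the marker identifies its cell type: over the clusters
    whose final annotation equals ``cell_type``, the fraction with median
    expression of ``gene`` above zero.  Returns ``None`` when no cluster
    carries the label (the statistic is undefined).
    """
    by_cluster = {p.cluster_id: p for p in profiles}
    matching = [c for c in calls if c.label == cell_type]
    if not matching:
        return None
    n_expressed = 0
    for call in matching:
        profile = by_cluster[call.cluster_id]
        if profile.median_expression.get(gene, 0.0) > 0.0:
            n_expressed += 1
    return n_expressed / len(matching)
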