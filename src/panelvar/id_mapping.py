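"""Ensembl-to-NCBI gene ID resolution.

Panels describe genes with Ensembl stable IDs; ClinVar keys its per-gene
counts by NCBI Gene ID.  A BioMart-style two-column export provides the
raw correspondence, which is many-to-many in places and one-sided in
others.  Resolution rules, in precedence order:

1. manual override (curated TSV) -> method ``manual``
2. single candidate              -> method ``unique``
3. several candidates            -> the one with the most total alleles in
   the variant matrix, compared at the latest month the candidates share
   (ties to the numerically smaller NCBI ID) -> method ``largest_count``
4. no candidate                  -> NA, method ``unmatched``

NA is a value, not an error: downstream joins count matched vs total genes
separately.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .clinvar_matrix import VariantMatrix
from .panel_history import GeneRecord

__all__ = [
    "Resolution",
    "MappingTable",
    "IdMap",
    "MatchReport",
    "AnnotatedGene",
    "load_mapping_table",
    "load_overrides",
    "resolve",
    "build_idmap",
    "annotate_gene_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one Ensembl ID."""

    ensembl_id: str
    ncbi_gene_id: int | None
    method: str  # unique | largest_count | manual | unmatched

    @property
    def matched(self) -> bool:
        return self.ncbi_gene_id is not None


@dataclass
class MappingTable:
    """Raw bidirectional multimap from a two-column ID export."""

    ens_to_ncbi: dict[str, set[int]] = field(default_factory=dict)
    ncbi_to_ens: dict[int, set[str]] = field(default_factory=dict)
    one_sided_ens: set[str] = field(default_factory=set)   # Ensembl ID, blank NCBI
    one_sided_ncbi: set[int] = field(default_factory=set)  # NCBI ID, blank Ensembl
    n_skipped: int = 0

    def add(self, ncbi: int | None, ens: str | None) -> None:
        if ncbi is not None and ens:
            self.ens_to_ncbi.setdefault(ens, set()).add(ncbi)
            self.ncbi_to_ens.setdefault(ncbi, set()).add(ens)
        elif ens:
            self.one_sided_ens.add(ens)
        elif ncbi is not None:
            self.one_sided_ncbi.add(ncbi)


def _looks_like_header(fields: list[str]) -> bool:
    first = fields[0].strip()
    if not first:
        return False
    try:
        int(first)
        return False
    except ValueError:
        return not first.upper().startswith("ENS")


def load_mapping_table(path: Path | str) -> MappingTable:
    """Read a BioMart-export style TSV of (NCBI gene ID, Ensembl gene stable ID).

    The header row is optional; rows with a blank cell become one-sided
    entries; rows that parse to neither ID are skipped with a warning count.
    """
    table = MappingTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r]
    if rows and _looks_like_header(rows[0]):
        rows = rows[1:]
    for row in rows:
        ncbi_raw = row[0].strip() if len(row) > 0 else ""
        ens_raw = row[1].strip() if len(row) > 1 else ""
        ncbi: int | None
        try:
            ncbi = int(ncbi_raw) if ncbi_raw else None
        except ValueError:
            ncbi = None
            if not ens_raw:
                table.n_skipped += 1
                continue
        if ncbi is None and not ens_raw:
            table.n_skipped += 1
            continue
        table.add(ncbi, ens_raw or None)
    if table.n_skipped:
        logger.warning("skipped %d malformed mapping rows", table.n_skipped)
    return table


def load_overrides(path: Path | str) -> dict[str, int]:
    """Read a manual-override TSV: ensembl_id, ncbi_gene_id[, evidence note]."""
    overrides: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or not row[0].strip():
                continue
            try:
                overrides[row[0].strip()] = int(row[1])
            except (ValueError, IndexError):
                continue  # header or junk row
    return overrides


def _largest_count(candidates: set[int], matrix: VariantMatrix) -> int:
    """Disambiguate by allele count at the latest month the candidates share."""
    present = {c: set(matrix.months_with_gene(c)) for c in candidates}
    in_matrix = {c for c, months in present.items() if months}
    if not in_matrix:
        return min(candidates)  # no data anywhere: deterministic tie-break
    common = set.intersection(*(present[c] for c in in_matrix))
    if common:
        month = max(common)
        scored = {c: matrix.get(month, c).total_alleles for c in in_matrix}
    else:
        # no shared month: compare each candidate at its own latest sighting
        scored = {
            c: matrix.get(max(present[c]), c).total_alleles for c in in_matrix
        }
    best = max(scored.values())
    return min(c for c, s in scored.items() if s == best)


def resolve(
    ensembl_id: str,
    table: MappingTable,
    matrix: VariantMatrix,
    overrides: Mapping[str, int] | None = None,
) -> Resolution:
    """Resolve one Ensembl gene ID to an NCBI Gene ID (or NA).

    Pure function of its inputs; see the module docstring for the
    precedence rules.
    """
    if overrides and ensembl_id in overrides:
        return Resolution(ensembl_id, overrides[ensembl_id], "manual")
    candidates = table.ens_to_ncbi.get(ensembl_id, set())
    if len(candidates) == 1:
        return Resolution(ensembl_id, next(iter(candidates)), "unique")
    if len(candidates) > 1:
        return Resolution(ensembl_id, _largest_count(candidates, matrix), "largest_count")
    return Resolution(ensembl_id, None, "unmatched")


class IdMap:
    """Resolved Ensembl -> NCBI map with per-gene provenance."""

    def __init__(self, entries: Mapping[str, Resolution]) -> None:
        self.entries = dict(entries)

    def __getitem__(self, ensembl_id: str) -> Resolution:
        return self.entries[ensembl_id]

    def get(self, ensembl_id: str | None) -> Resolution | None:
        if ensembl_id is None:
            return None
        return self.entries.get(ensembl_id)

    def __len__(self) -> int:
        return len(self.entries)

    def to_rows(self) -> list[dict]:
        return [
            {"ensembl_id": e, "ncbi_gene_id": r.ncbi_gene_id
             if r.ncbi_gene_id is not None else "NA", "method": r.method}
            for e, r in sorted(self.entries.items())
        ]


def build_idmap(
    ensembl_ids: Iterable[str],
    table: MappingTable,
    matrix: VariantMatrix,
    overrides: Mapping[str, int] | None = None,
) -> IdMap:
    """Resolve every Ensembl ID once; each appears exactly once in the map."""
    return IdMap({e: resolve(e, table, matrix, overrides) for e in set(ensembl_ids)})


@dataclass(frozen=True)
class AnnotatedGene:
    record: GeneRecord
    resolution: Resolution | None  # None when the record has no Ensembl ID

    @property
    def ncbi_gene_id(self) -> int | None:
        return self.resolution.ncbi_gene_id if self.resolution else None

    @property
    def matched(self) -> bool:
        return self.ncbi_gene_id is not None


@dataclass
class MatchReport:
    n_total: int
    n_matched: int
    unmatched_symbols: list[str]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_matched": self.n_matched,
            "unmatched_symbols": sorted(self.unmatched_symbols),
        }


def annotate_gene_list(
    genes: Iterable[GeneRecord], idmap: IdMap
) -> tuple[list[AnnotatedGene], MatchReport]:
    """Attach resolutions to a gene list and report matched vs total counts.

    Feeds the dual-count convention used throughout the joined outputs:
    "matched (total)" — matched <= total always.
    """
    annotated: list[AnnotatedGene] = []
    unmatched: list[str] = []
    for rec in genes:
        res = idmap.get(rec.ensembl_id)
        ag = AnnotatedGene(rec, res)
        annotated.append(ag)
        if not ag.matched:
            unmatched.append(rec.symbol)
    return annotated, MatchReport(len(annotated), len(annotated) - len(unmatched), unmatched)
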