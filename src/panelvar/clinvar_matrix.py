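"""Monthly ClinVar gene-summary files and the month x gene variant-count matrix.

ClinVar's per-gene release file ("gene specific summary") is tab-delimited
with '#'-prefixed header lines; the columns consumed here are Symbol, GeneID
(NCBI), Total_alleles and Alleles_reported_Pathogenic_Likely_pathogenic
(P/LP).  One file per month is parsed and assembled into a
:class:`VariantMatrix` keyed by (month, NCBI gene ID).

A gene absent from a month's file is *missing*, never zero: ClinVar omits
genes without submissions, so absence is indistinguishable from schema drift
and must stay visible downstream.  Note the P/LP column excludes variants
overlapping other genes while Total_alleles does not, so plp/total ratios
are approximate.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .months import MonthKey

__all__ = [
    "GeneVariantCounts",
    "ParseReport",
    "VariantMatrix",
    "SummaryFormatError",
    "parse_gene_specific_summary",
    "assign_months",
    "build_matrix",
    "load_matrix_from_files",
]

logger = logging.getLogger(__name__)

#: canonical column name -> lowercased aliases accepted in file headers
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "symbol": ("symbol",),
    "gene_id": ("geneid", "gene_id"),
    "total_alleles": ("total_alleles",),
    "plp_alleles": (
        "alleles_reported_pathogenic_likely_pathogenic",
        "number_of_alleles_reported_pathogenic_likely_pathogenic",
    ),
}


class SummaryFormatError(ValueError):
    """A gene summary file lacks a required column or any data."""


@dataclass(frozen=True)
class GeneVariantCounts:
    """Allele counts for one gene in one monthly file."""

    ncbi_gene_id: int
    symbol: str
    total_alleles: int
    plp_alleles: int

    def __post_init__(self) -> None:
        if self.ncbi_gene_id <= 0:
            raise ValueError(f"NCBI gene ID must be positive, got {self.ncbi_gene_id}")
        if not 0 <= self.plp_alleles <= self.total_alleles:
            raise ValueError(
                f"{self.symbol}: P/LP alleles {self.plp_alleles} outside "
                f"[0, total_alleles={self.total_alleles}]"
            )


@dataclass
class ParseReport:
    """Row-level accounting for one parsed summary file."""

    path: str
    n_rows: int = 0
    n_kept: int = 0
    n_skipped_no_id: int = 0       # GeneID == -1 (multi-gene aggregate rows)
    n_skipped_unparseable: int = 0
    n_rejected_invariant: int = 0  # plp > total or negative counts
    rejected_symbols: list[str] = field(default_factory=list)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _match_columns(header_fields: Sequence[str],
                   legacy_names: Mapping[str, str] | None) -> dict[str, int]:
    """Map canonical column names to positions, case-insensitively."""
    norm = [f.strip().lstrip("#").strip().lower() for f in header_fields]
    extra = {k.lower(): v for k, v in (legacy_names or {}).items()}
    positions: dict[str, int] = {}
    for canonical, aliases in REQUIRED_COLUMNS.items():
        for i, name in enumerate(norm):
            if name in aliases or extra.get(name) == canonical:
                positions[canonical] = i
                break
        else:
            raise SummaryFormatError(
                f"required column {canonical!r} not found "
                f"(accepted headers: {', '.join(aliases)})"
            )
    return positions


def parse_gene_specific_summary(
    path: Path | str,
    legacy_names: Mapping[str, str] | None = None,
) -> tuple[list[GeneVariantCounts], ParseReport]:
    """Parse one monthly gene summary file (plain or gzip).

    The last '#'-prefixed line is taken as the column header; column names
    are matched case-insensitively after stripping '#' and whitespace, and
    ``legacy_names`` can map historical headers onto canonical ones.  Rows
    with GeneID -1, unparseable counts, or P/LP > total are dropped and
    accounted for in the :class:`ParseReport`.
    """
    path = Path(path)
    header: list[str] | None = None
    data_lines: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = line.rstrip("\n").split("\t")
            elif line.strip():
                data_lines.append(line.rstrip("\n"))
    if header is None:
        # headerless dialect: first data line is the header
        if not data_lines:
            raise SummaryFormatError(f"{path}: empty file")
        header, data_lines = data_lines[0].split("\t"), data_lines[1:]
    if not data_lines:
        raise SummaryFormatError(f"{path}: no data rows")

    pos = _match_columns(header, legacy_names)
    report = ParseReport(path=str(path))
    records: list[GeneVariantCounts] = []
    for line in data_lines:
        report.n_rows += 1
        fields = line.split("\t")
        try:
            gene_id = int(fields[pos["gene_id"]])
        except (ValueError, IndexError):
            report.n_skipped_unparseable += 1
            continue
        if gene_id == -1:
            report.n_skipped_no_id += 1
            continue
        symbol = fields[pos["symbol"]]
        try:
            total = int(fields[pos["total_alleles"]])
            plp = int(fields[pos["plp_alleles"]])
        except (ValueError, IndexError):
            report.n_skipped_unparseable += 1
            continue
        try:
            records.append(GeneVariantCounts(gene_id, symbol, total, plp))
        except ValueError:
            report.n_rejected_invariant += 1
            report.rejected_symbols.append(symbol)
            continue
        report.n_kept += 1
    return records, report


# ---------------------------------------------------------------------------
# month assignment
# ---------------------------------------------------------------------------

_DEFAULT_DATE_RE = re.compile(r"(\d{4})-(\d{2})(?:-(\d{2}))?")


def _file_date(name: str, pattern: re.Pattern) -> date:
    m = pattern.search(Path(name).name)
    if m is None:
        raise ValueError(f"cannot extract a date from filename {name!r}")
    year, month = int(m.group(1)), int(m.group(2))
    if m.lastindex and m.lastindex >= 3 and m.group(3):
        return date(year, month, int(m.group(3)))
    # month-only names anchor to the month end, matching the snapshot cutoff
    return MonthKey(year, month).last_day()


def assign_months(
    files: Sequence[str],
    panel_months: Sequence[MonthKey],
    date_pattern: str | re.Pattern = _DEFAULT_DATE_RE,
    tolerance_days: int = 45,
) -> dict[MonthKey, str]:
    """Map each panel month to the summary file dated nearest its month-end.

    Filenames carry a date (``YYYY-MM`` prefix by default, an explicit day
    honoured when present).  Ties break to the earlier file.  A month with
    no file within ``tolerance_days`` of its end is an error.
    """
    pattern = re.compile(date_pattern) if isinstance(date_pattern, str) else date_pattern
    dated = sorted((_file_date(f, pattern), f) for f in files)
    if not dated:
        raise ValueError("no summary files supplied")
    mapping: dict[MonthKey, str] = {}
    unmatched: list[MonthKey] = []
    for month in panel_months:
        cutoff = month.last_day()
        best = min(dated, key=lambda df: (abs((df[0] - cutoff).days), df[0]))
        if abs((best[0] - cutoff).days) > tolerance_days:
            unmatched.append(month)
        else:
            mapping[month] = best[1]
    if unmatched:
        raise ValueError(
            "no summary file within tolerance for months: "
            + ", ".join(str(m) for m in unmatched)
        )
    return mapping


# ---------------------------------------------------------------------------
# the matrix
# ---------------------------------------------------------------------------

class VariantMatrix:
    """Month x gene matrix of allele counts, with missing distinct from zero.

    Lookup of an absent (month, gene) pair returns ``None``; sums skip
    missing cells and report how many requested genes were missing.
    """

    def __init__(
        self,
        cells: Mapping[tuple[MonthKey, int], GeneVariantCounts],
        provenance: Mapping[MonthKey, str] | None = None,
    ) -> None:
        self._cells = dict(cells)
        self.months: list[MonthKey] = sorted({m for m, _ in self._cells})
        self.provenance: dict[MonthKey, str] = dict(provenance or {})

    def get(self, month: MonthKey, gene_id: int) -> GeneVariantCounts | None:
        return self._cells.get((month, gene_id))

    def genes_in(self, month: MonthKey) -> set[int]:
        return {g for m, g in self._cells if m == month}

    def all_genes(self) -> set[int]:
        return {g for _, g in self._cells}

    def months_with_gene(self, gene_id: int) -> list[MonthKey]:
        return sorted(m for m, g in self._cells if g == gene_id)

    def _sum(self, attr: str, month: MonthKey,
             genes: Iterable[int] | None) -> tuple[int, int]:
        if month not in self.months:
            raise KeyError(f"matrix has no data for month {month}")
        if genes is None:
            gene_ids = self.genes_in(month)
        else:
            gene_ids = set(genes)
        total, missing = 0, 0
        for g in gene_ids:
            cell = self._cells.get((month, g))
            if cell is None:
                missing += 1
            else:
                total += getattr(cell, attr)
        return total, missing

    def total_plp(self, month: MonthKey,
                  genes: Iterable[int] | None = None) -> tuple[int, int]:
        """Sum of P/LP alleles over ``genes`` (all genes when None).

        Returns ``(sum, n_missing)`` where ``n_missing`` counts requested
        genes absent from that month's file.
        """
        return self._sum("plp_alleles", month, genes)

    def total_alleles(self, month: MonthKey,
                      genes: Iterable[int] | None = None) -> tuple[int, int]:
        """Sum of total alleles over ``genes``; same contract as total_plp."""
        return self._sum("total_alleles", month, genes)

    # -- serialisation ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"month": str(m), "gene_id": g, "symbol": c.symbol,
             "total_alleles": c.total_alleles, "plp_alleles": c.plp_alleles}
            for (m, g), c in sorted(self._cells.items())
        ]
        return pd.DataFrame(
            rows, columns=["month", "gene_id", "symbol", "total_alleles", "plp_alleles"]
        )

    def write_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   provenance: Mapping[MonthKey, str] | None = None) -> "VariantMatrix":
        cells = {}
        for row in df.itertuples(index=False):
            m = MonthKey.parse(str(row.month))
            cells[(m, int(row.gene_id))] = GeneVariantCounts(
                int(row.gene_id), str(row.symbol),
                int(row.total_alleles), int(row.plp_alleles),
            )
        return cls(cells, provenance)

    @classmethod
    def read_tsv(cls, path: Path | str) -> "VariantMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_matrix(
    monthly_records: Mapping[MonthKey, Sequence[GeneVariantCounts]],
    provenance: Mapping[MonthKey, str] | None = None,
) -> VariantMatrix:
    """Assemble parsed monthly record lists into a :class:`VariantMatrix`.

    A duplicated GeneID within one month keeps the row with the larger
    total allele count and logs a warning.
    """
    if not monthly_records:
        raise ValueError("no monthly records supplied")
    cells: dict[tuple[MonthKey, int], GeneVariantCounts] = {}
    for month, records in monthly_records.items():
        for rec in records:
            key = (month, rec.ncbi_gene_id)
            old = cells.get(key)
            if old is not None:
                logger.warning(
                    "duplicate GeneID %d in %s (%s vs %s); keeping larger total",
                    rec.ncbi_gene_id, month, old.symbol, rec.symbol,
                )
                if rec.total_alleles <= old.total_alleles:
                    continue
            cells[key] = rec
    return VariantMatrix(cells, provenance)


def load_matrix_from_files(
    mapping: Mapping[MonthKey, str],
    legacy_names: Mapping[str, str] | None = None,
) -> tuple[VariantMatrix, list[ParseReport]]:
    """Parse every (month -> filename) pair and build the matrix."""
    monthly: dict[MonthKey, list[GeneVariantCounts]] = {}
    reports = []
    for month, fname in sorted(mapping.items()):
        records, report = parse_gene_specific_summary(fname, legacy_names)
        monthly[month] = records
        reports.append(report)
    return build_matrix(monthly, provenance=dict(mapping)), reports
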