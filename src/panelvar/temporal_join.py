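"""Join panel gene information with the monthly variant matrix.

Two modes, mirroring the two questions a diagnostic laboratory asks:

*Static gene list mode* takes a fixed, annotated gene list (e.g. the union
of diagnostic genes across panels at the end of the window) and crosses it
with every month of the matrix, producing the per-gene-per-month table used
for per-gene change summaries and rankings.

*Evolving panel mode* replays history: for each month it takes the panel
version actually in force, resolves its genes, and sums that month's P/LP
alleles over that month's diagnostic genes — approximating the information
available to curators at that point in time.  Matched and total gene counts
are reported separately throughout (the "519 (521)" dual-count convention),
since not every Ensembl ID resolves to an NCBI gene present in ClinVar.

The chosen NCBI ID per gene is fixed by the ID map (no month-to-month
identity flapping); per-month matrix presence decides whether the gene
contributes that month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .clinvar_matrix import VariantMatrix
from .id_mapping import AnnotatedGene, IdMap
from .months import MonthKey
from .panel_history import MonthlyPanelSeries

__all__ = ["StaticGeneTable", "JoinedSeries", "static_mode", "evolving_mode"]


class StaticGeneTable:
    """Full cross of a fixed gene list with the matrix months.

    Backed by a long-format frame with one row per (gene, month); cells for
    unresolved genes or months where ClinVar lacks the gene are flagged
    ``missing`` (counts left as NA), never zeroed.
    """

    COLUMNS = [
        "symbol", "ensembl_id", "ncbi_gene_id", "method",
        "month", "total_alleles", "plp_alleles", "missing",
    ]

    def __init__(self, frame: pd.DataFrame, months: list[MonthKey]):
        self.frame = frame
        self.months = months

    def column_totals(self, month: MonthKey) -> tuple[int, int, int]:
        """(total_alleles, plp_alleles, n_missing) summed over the list at one month."""
        sub = self.frame[self.frame["month"] == str(month)]
        present = sub[~sub["missing"]]
        return (
            int(present["total_alleles"].sum()),
            int(present["plp_alleles"].sum()),
            int(sub["missing"].sum()),
        )

    def gene_series(self, symbol: str) -> pd.DataFrame:
        return self.frame[self.frame["symbol"] == symbol].sort_values("month")

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "StaticGeneTable":
        frame = pd.read_csv(path, sep="\t")
        months = sorted({MonthKey.parse(m) for m in frame["month"].unique()})
        return cls(frame, months)


def static_mode(
    gene_list: Sequence[AnnotatedGene], matrix: VariantMatrix
) -> StaticGeneTable:
    """Cross an annotated gene list with every matrix month."""
    if not gene_list:
        raise ValueError("static mode requires a non-empty gene list")
    rows = []
    for ag in gene_list:
        rec = ag.record
        for month in matrix.months:
            cell = matrix.get(month, ag.ncbi_gene_id) if ag.matched else None
            rows.append({
                "symbol": rec.symbol,
                "ensembl_id": rec.ensembl_id or "",
                "ncbi_gene_id": ag.ncbi_gene_id if ag.matched else pd.NA,
                "method": ag.resolution.method if ag.resolution else "no_ensembl_id",
                "month": str(month),
                "total_alleles": cell.total_alleles if cell else pd.NA,
                "plp_alleles": cell.plp_alleles if cell else pd.NA,
                "missing": cell is None,
            })
    frame = pd.DataFrame(rows, columns=StaticGeneTable.COLUMNS)
    return StaticGeneTable(frame, list(matrix.months))


@dataclass
class JoinedSeries:
    """Per-month joined panel + variant summary for one panel."""

    panel_id: int
    frame: pd.DataFrame  # one row per month

    COLUMNS = [
        "month", "panel_version", "n_genes_total", "n_genes_matched",
        "n_diag_total", "n_diag_matched", "total_alleles_all_genes",
        "plp_in_diag",
    ]

    def row(self, month: MonthKey) -> pd.Series:
        sub = self.frame[self.frame["month"] == str(month)]
        if sub.empty:
            raise KeyError(f"joined series has no row for {month}")
        return sub.iloc[0]

    def plp_series(self) -> tuple[list[MonthKey], list[int]]:
        months = [MonthKey.parse(m) for m in self.frame["month"]]
        return months, [int(v) for v in self.frame["plp_in_diag"]]

    def diag_series(self) -> tuple[list[MonthKey], list[int]]:
        months = [MonthKey.parse(m) for m in self.frame["month"]]
        return months, [int(v) for v in self.frame["n_diag_matched"]]

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def evolving_mode(
    series: MonthlyPanelSeries, matrix: VariantMatrix, idmap: IdMap
) -> JoinedSeries:
    """Replay the panel's monthly snapshots against the matrix.

    For each month: the diagnostic genes of that month's snapshot are
    resolved through ``idmap`` and their P/LP alleles summed from that
    month's matrix column.  ``total_alleles_all_genes`` covers matched
    panel genes of any rating; ``plp_in_diag`` covers matched diagnostic
    genes only.  A series month absent from the matrix is an error naming
    the month.
    """
    missing_months = [m for m in series.month_list() if m not in matrix.months]
    if missing_months:
        raise KeyError(
            "variant matrix lacks months required by the panel series: "
            + ", ".join(str(m) for m in missing_months)
        )
    rows = []
    for month in series.month_list():
        snap = series.snapshot(month)
        gene_recs = snap.gene_records()
        diag_recs = [r for r in gene_recs if r.is_diagnostic]

        def _matched_ids(recs):
            ids = []
            for r in recs:
                res = idmap.get(r.ensembl_id)
                if res is not None and res.matched and matrix.get(month, res.ncbi_gene_id):
                    ids.append(res.ncbi_gene_id)
            return ids

        all_ids = _matched_ids(gene_recs)
        diag_ids = _matched_ids(diag_recs)
        total_all, _ = matrix.total_alleles(month, all_ids) if all_ids else (0, 0)
        plp_diag, _ = matrix.total_plp(month, diag_ids) if diag_ids else (0, 0)
        rows.append({
            "month": str(month),
            "panel_version": snap.version,
            "n_genes_total": len(gene_recs),
            "n_genes_matched": len(all_ids),
            "n_diag_total": len(diag_recs),
            "n_diag_matched": len(diag_ids),
            "total_alleles_all_genes": total_all,
            "plp_in_diag": plp_diag,
        })
    return JoinedSeries(series.panel_id, pd.DataFrame(rows, columns=JoinedSeries.COLUMNS))
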