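"""Versioned gene-panel histories: parsing, monthly snapshots, change classification.

A clinical virtual gene panel (PanelApp / PanelApp Australia style) is a
curated list of genes, each carrying an ordinal confidence rating 0-3 where
3 ("Green") means the gene is of diagnostic grade for the panel's clinical
indication.  Panels are versioned: every curation action produces a new
dated version.  This module ingests those version payloads, selects one
representative snapshot per calendar month (the version in force at 23:59:59
on the last day of the month, UTC), and classifies the gene-status
transitions between consecutive monthly snapshots.

Gene identity across versions is the Ensembl gene ID when present, falling
back to the symbol, so a symbol rename with a stable Ensembl ID is not a
change event.  Entries that are not genes (short tandem repeats, CNV
regions) are parsed and kept in snapshots but excluded from every count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .months import MonthKey, month_range

__all__ = [
    "DIAGNOSTIC_RATING",
    "GeneRecord",
    "PanelSnapshot",
    "MonthlyPanelSeries",
    "ChangeSet",
    "PanelParseError",
    "parse_panel_version",
    "load_panel_versions",
    "select_monthly_snapshots",
    "classify_changes",
    "diagnostic_count",
    "union_diagnostic_list",
    "changesets_to_rows",
]

#: Confidence level that marks a gene as diagnostic grade ("Green").
DIAGNOSTIC_RATING = 3


class PanelParseError(ValueError):
    """A panel version payload is missing or malforms a required field."""


@dataclass(frozen=True)
class GeneRecord:
    """One entry of a panel version.

    ``rating`` is the ordinal confidence level 0-3; ``entity_type`` is
    ``gene`` for ordinary genes, ``str`` / ``region`` for repeat expansions
    and CNV regions, which never contribute to gene statistics.
    """

    symbol: str
    ensembl_id: str | None
    entity_type: str = "gene"
    rating: int = 0

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.rating not in (0, 1, 2, 3):
            raise ValueError(f"rating must be in 0..3, got {self.rating}")

    @property
    def is_gene(self) -> bool:
        return self.entity_type == "gene"

    @property
    def is_diagnostic(self) -> bool:
        return self.is_gene and self.rating == DIAGNOSTIC_RATING

    @property
    def key(self) -> str:
        """Identity used to track this entry across versions."""
        return self.ensembl_id if self.ensembl_id else f"symbol:{self.symbol}"


@dataclass
class PanelSnapshot:
    """One dated, versioned panel: its entries keyed by symbol."""

    panel_id: int
    source: str  # "AUS" | "UK"
    version: str
    timestamp: datetime
    genes: dict[str, GeneRecord] = field(default_factory=dict)

    def gene_records(self) -> list[GeneRecord]:
        """Entries of entity type ``gene`` only (the countable ones)."""
        return [g for g in self.genes.values() if g.is_gene]

    def diagnostic_records(self) -> list[GeneRecord]:
        return [g for g in self.genes.values() if g.is_diagnostic]

    def by_key(self) -> dict[str, GeneRecord]:
        """Gene-type entries keyed by tracking identity (Ensembl ID or symbol)."""
        return {g.key: g for g in self.gene_records()}


@dataclass
class MonthlyPanelSeries:
    """One snapshot per calendar month, launch month onwards, gaps carried forward."""

    panel_id: int
    months: dict[MonthKey, PanelSnapshot]
    launch_month: MonthKey

    def snapshot(self, month: MonthKey) -> PanelSnapshot:
        try:
            return self.months[month]
        except KeyError:
            raise KeyError(
                f"panel {self.panel_id} has no snapshot for {month} "
                f"(series covers {self.launch_month}..{max(self.months)})"
            ) from None

    def month_list(self) -> list[MonthKey]:
        return sorted(self.months)


@dataclass
class ChangeSet:
    """Classified gene-status transitions between two consecutive monthly snapshots.

    The six symbol lists are pairwise disjoint and satisfy the conservation
    identity::

        diag(curr) - diag(prev) == |added_diagnostic| + |upgraded|
                                   - |downgraded| - |removed_diagnostic|
    """

    month: MonthKey
    added_diagnostic: list[str] = field(default_factory=list)
    upgraded: list[str] = field(default_factory=list)
    downgraded: list[str] = field(default_factory=list)
    removed_diagnostic: list[str] = field(default_factory=list)
    added_nondiagnostic: list[str] = field(default_factory=list)
    removed_nondiagnostic: list[str] = field(default_factory=list)

    CATEGORIES = (
        "added_diagnostic",
        "upgraded",
        "downgraded",
        "removed_diagnostic",
        "added_nondiagnostic",
        "removed_nondiagnostic",
    )

    @property
    def net_diagnostic_change(self) -> int:
        """Net change in diagnostic-gene count implied by the event counts."""
        return (
            len(self.added_diagnostic)
            + len(self.upgraded)
            - len(self.downgraded)
            - len(self.removed_diagnostic)
        )

    def is_empty(self) -> bool:
        return all(not getattr(self, c) for c in self.CATEGORIES)

    def to_dict(self) -> dict:
        d = {"month": str(self.month)}
        d.update({c: sorted(getattr(self, c)) for c in self.CATEGORIES})
        return d


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        # PanelApp serialises UTC; a naive stamp is taken as UTC.
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


def _parse_rating(raw) -> int:
    try:
        r = int(raw)
    except (TypeError, ValueError):
        return 0
    return r if r in (0, 1, 2, 3) else 0


def parse_panel_version(document: Mapping, source: str = "AUS") -> PanelSnapshot:
    """Parse one PanelApp-style version payload into a :class:`PanelSnapshot`.

    Consumed fields: ``version``, ``version_created``, ``id`` and per entry
    ``gene_data.gene_symbol``, ``gene_data.ensembl_id_or_equivalent``,
    ``entity_type``, ``confidence_level``.  Entries whose entity type is not
    ``gene`` are retained but excluded from all counting operations.

    Raises :class:`PanelParseError` naming the field when ``version`` or
    ``version_created`` is missing, or listing the symbol on a duplicate.
    """
    version = document.get("version")
    if not version:
        raise PanelParseError("panel payload is missing required field 'version'")
    raw_ts = document.get("version_created")
    if not raw_ts:
        raise PanelParseError("panel payload is missing required field 'version_created'")
    timestamp = _parse_timestamp(raw_ts)
    panel_id = int(document.get("id", -1))

    genes: dict[str, GeneRecord] = {}
    for entry in document.get("genes", []):
        gene_data = entry.get("gene_data") or {}
        symbol = gene_data.get("gene_symbol") or entry.get("gene_symbol")
        if not symbol:
            raise PanelParseError("panel entry without a gene_symbol")
        if symbol in genes:
            raise PanelParseError(f"duplicate symbol in panel version {version}: {symbol}")
        ensembl = gene_data.get("ensembl_id_or_equivalent") or None
        genes[symbol] = GeneRecord(
            symbol=symbol,
            ensembl_id=ensembl,
            entity_type=entry.get("entity_type", "gene"),
            rating=_parse_rating(entry.get("confidence_level")),
        )
    return PanelSnapshot(
        panel_id=panel_id, source=source, version=str(version),
        timestamp=timestamp, genes=genes,
    )


def load_panel_versions(path: Path | str, source: str = "AUS") -> list[PanelSnapshot]:
    """Load every ``*.json`` version payload under ``path``, sorted by timestamp."""
    path = Path(path)
    files = sorted(path.glob("*.json")) if path.is_dir() else [path]
    snaps = [parse_panel_version(json.loads(f.read_text()), source=source) for f in files]
    snaps.sort(key=lambda s: s.timestamp)
    return snaps


# ---------------------------------------------------------------------------
# monthly snapshot selection
# ---------------------------------------------------------------------------

def select_monthly_snapshots(
    versions: Sequence[PanelSnapshot],
    start: MonthKey | None = None,
    end: MonthKey | None = None,
) -> MonthlyPanelSeries:
    """Pick one representative snapshot per month from a version history.

    The representative for month *m* is the latest version whose timestamp
    is on or before 23:59:59 UTC on the last day of *m*; a month with no new
    version carries the previous month's snapshot forward.  The window
    defaults to the months of the first and last versions.  A window that
    starts before the first version is an error: there is nothing to carry
    forward into the past.
    """
    if not versions:
        raise ValueError("no panel versions supplied")
    ordered = sorted(versions, key=lambda s: s.timestamp)
    for a, b in zip(ordered, ordered[1:]):
        if b.timestamp <= a.timestamp:
            raise ValueError(
                f"version timestamps must be strictly increasing "
                f"({a.version} at {a.timestamp} vs {b.version} at {b.timestamp})"
            )
    first_month = MonthKey.from_date(ordered[0].timestamp)
    start = start or first_month
    end = end or MonthKey.from_date(ordered[-1].timestamp)
    if start < first_month:
        raise ValueError(
            f"window starts {start}, before the first panel version ({first_month}); "
            "cannot carry a snapshot backwards in time"
        )

    months: dict[MonthKey, PanelSnapshot] = {}
    i = -1  # index of latest version at or before the running cutoff
    for m in month_range(start, end):
        cutoff = m.end_instant()
        while i + 1 < len(ordered) and ordered[i + 1].timestamp <= cutoff:
            i += 1
        months[m] = ordered[i]  # i >= 0 guaranteed by the window check
    return MonthlyPanelSeries(
        panel_id=ordered[0].panel_id, months=months, launch_month=start
    )


# ---------------------------------------------------------------------------
# change classification
# ---------------------------------------------------------------------------

def classify_changes(prev: PanelSnapshot, curr: PanelSnapshot,
                     month: MonthKey | None = None) -> ChangeSet:
    """Classify gene transitions between two consecutive monthly snapshots.

    Genes are matched across snapshots by Ensembl ID when available, else
    symbol; only entity-type ``gene`` entries participate.  Every gene falls
    in exactly one of the six categories or is unchanged.
    """
    month = month or MonthKey.from_date(curr.timestamp)
    before = prev.by_key()
    after = curr.by_key()
    cs = ChangeSet(month=month)
    for key, rec in after.items():
        old = before.get(key)
        if old is None:
            (cs.added_diagnostic if rec.is_diagnostic else cs.added_nondiagnostic
             ).append(rec.symbol)
        elif rec.is_diagnostic and not old.is_diagnostic:
            cs.upgraded.append(rec.symbol)
        elif old.is_diagnostic and not rec.is_diagnostic:
            cs.downgraded.append(rec.symbol)
    for key, old in before.items():
        if key not in after:
            (cs.removed_diagnostic if old.is_diagnostic else cs.removed_nondiagnostic
             ).append(old.symbol)
    for cat in cs.CATEGORIES:
        getattr(cs, cat).sort()
    return cs


def diagnostic_count(snapshot: PanelSnapshot) -> int:
    """Number of diagnostic-grade (rating-3) gene entries in a snapshot."""
    return len(snapshot.diagnostic_records())


def union_diagnostic_list(
    serieses: Iterable[MonthlyPanelSeries], at: MonthKey
) -> list[GeneRecord]:
    """Union of diagnostic genes across panels at one month.

    Deduplicated by Ensembl ID when present, else symbol; the first record
    seen for an identity wins.  Raises :class:`KeyError` naming any panel
    that does not cover ``at``.
    """
    seen: dict[str, GeneRecord] = {}
    for series in serieses:
        snap = series.snapshot(at)  # KeyError names the panel
        for rec in snap.diagnostic_records():
            seen.setdefault(rec.key, rec)
    return sorted(seen.values(), key=lambda r: r.symbol)


def changesets_to_rows(changesets: Iterable[ChangeSet], panel_id: int) -> list[dict]:
    """Long-format rows (month, panel_id, category, symbol) for TSV export."""
    rows = []
    for cs in changesets:
        for cat in ChangeSet.CATEGORIES:
            for symbol in getattr(cs, cat):
                rows.append(
                    {"month": str(cs.month), "panel_id": panel_id,
                     "category": cat, "symbol": symbol}
                )
    return rows
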