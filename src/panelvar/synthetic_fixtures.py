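"""Ground-truthed synthetic inputs: panel histories, monthly gene summaries, ID maps.

Everything this package consumes can be emulated offline: a versioned panel
JSON history, monthly ClinVar-dialect gene summary files, and a BioMart-style
ID mapping table, all generated from a :class:`FixtureSpec` whose injected
events (gene additions/upgrades/downgrades/removals, P/LP steps and
declines, unmatched genes, ID clashes) are recorded in a machine-readable
:class:`EventLog`.  The full pipeline run on a fixture must recover that log
exactly — this is the package's strongest end-to-end check.

Baseline P/LP counts grow geometrically at a mean 1.8% per month with
multiplicative noise, the typical pace observed for clinically curated gene
cohorts, with per-gene monthly growth clipped below the conventional 5%
burst threshold so that only injected events can produce a burst.  The same
spec and seed always regenerate byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .months import MonthKey, month_range

__all__ = [
    "EVENT_KINDS",
    "Event",
    "FixtureSpec",
    "EventLog",
    "FixtureResult",
    "generate",
    "correlated_series",
]

EVENT_KINDS = frozenset({
    "add_diag", "upgrade", "downgrade", "remove_diag",
    "plp_step", "plp_decline", "unmatched_gene", "id_clash",
})

#: event kinds that trigger a new panel version
_PANEL_KINDS = frozenset({"add_diag", "upgrade", "downgrade", "remove_diag"})


@dataclass(frozen=True)
class Event:
    """One injected change.

    ``gene`` is a panel symbol; ``None`` lets the generator pick a suitable
    gene deterministically.  ``magnitude`` is the P/LP count delta for
    ``plp_step`` (added) and ``plp_decline`` (subtracted); ignored otherwise.
    """

    month: MonthKey
    kind: str
    gene: str | None = None
    magnitude: int = 0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; spec + seed fully determine output."""

    n_genes: int = 50
    n_months: int = 24
    launch_month: MonthKey = MonthKey(2018, 4)
    seed: int = 0
    events: list[Event] = field(default_factory=list)
    monthly_growth: float = 0.018   # mean baseline P/LP growth per month
    growth_sd: float = 0.006
    growth_cap: float = 0.045       # keeps baseline below the 5% burst threshold
    frac_diagnostic: float = 0.55
    frac_rating2: float = 0.25
    panel_id: int = 402
    source: str = "AUS"
    include_str_entry: bool = True
    n_extra_clinvar_genes: int = 10

    def months(self) -> list[MonthKey]:
        return month_range(self.launch_month, self.launch_month.plus(self.n_months - 1))


@dataclass
class EventLog:
    """Realised events with exact months and count deltas."""

    entries: list[dict] = field(default_factory=list)

    def of_kind(self, *kinds: str) -> list[dict]:
        return [e for e in self.entries if e["kind"] in kinds]

    def to_json(self) -> str:
        return json.dumps({"events": self.entries}, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: Path | str) -> "EventLog":
        return cls(json.loads(Path(path).read_text())["events"])


@dataclass
class FixtureResult:
    """Generated files plus the ground truth a test needs to verify recovery."""

    spec: FixtureSpec
    out_dir: Path
    panels_dir: Path
    clinvar_dir: Path
    mapping_file: Path
    event_log_file: Path
    event_log: EventLog
    # truth tables
    gene_info: dict[str, tuple[str | None, int | None]]  # symbol -> (ensembl, ncbi)
    diag_symbols: dict[MonthKey, set[str]]
    counts: dict[MonthKey, dict[int, tuple[int, int]]]   # month -> ncbi -> (total, plp)

    def diag_counts(self) -> dict[MonthKey, int]:
        return {m: len(s) for m, s in self.diag_symbols.items()}

    def panel_plp_total(self, month: MonthKey) -> int:
        """Ground-truth P/LP total over that month's diagnostic genes."""
        total = 0
        for sym in self.diag_symbols[month]:
            ncbi = self.gene_info[sym][1]
            if ncbi is not None and ncbi in self.counts[month]:
                total += self.counts[month][ncbi][1]
        return total


class _PanelState:
    """Mutable panel membership during event replay."""

    def __init__(self) -> None:
        self.entries: dict[str, dict] = {}  # symbol -> {ensembl, rating, entity_type}

    def add(self, symbol: str, ensembl: str | None, rating: int,
            entity_type: str = "gene") -> None:
        self.entries[symbol] = {
            "symbol": symbol, "ensembl": ensembl,
            "rating": rating, "entity_type": entity_type,
        }

    def diag_symbols(self) -> set[str]:
        return {
            s for s, e in self.entries.items()
            if e["entity_type"] == "gene" and e["rating"] == 3
        }


def _validate_events(spec: FixtureSpec) -> None:
    months = spec.months()
    for ev in spec.events:
        if ev.month not in months:
            raise ValueError(f"event {ev.kind} at {ev.month} outside fixture window")
        if ev.kind in _PANEL_KINDS | {"plp_step", "plp_decline"} and ev.month == spec.launch_month:
            raise ValueError(
                f"event {ev.kind} at launch month {ev.month}: change events need "
                "a preceding month to diff against"
            )
        if ev.kind in {"plp_step", "plp_decline"} and ev.magnitude <= 0:
            raise ValueError(f"{ev.kind} needs a positive magnitude")


def _panel_document(spec: FixtureSpec, state: _PanelState,
                    version: str, timestamp: str) -> dict:
    genes = []
    for symbol in sorted(state.entries):
        e = state.entries[symbol]
        genes.append({
            "entity_type": e["entity_type"],
            "confidence_level": str(e["rating"]),
            "gene_data": {
                "gene_symbol": e["symbol"],
                "ensembl_id_or_equivalent": e["ensembl"],
            },
        })
    return {
        "id": spec.panel_id,
        "version": version,
        "version_created": timestamp,
        "genes": genes,
    }


def _pick(state: _PanelState, predicate, taken: set[str], what: str) -> str:
    for symbol in sorted(state.entries):
        if symbol not in taken and predicate(state.entries[symbol]):
            return symbol
    raise ValueError(f"no eligible gene for {what} event")


def generate(spec: FixtureSpec, out_dir: Path | str) -> FixtureResult:
    """Write the full synthetic dataset under ``out_dir`` and return its truth.

    Layout: ``panels/`` (one JSON per panel version), ``clinvar/`` (one TSV
    per month, named ``YYYY-MM.txt``), ``mapping.tsv``, ``event_log.json``.
    Re-running with the same spec and seed is byte-identical.
    """
    _validate_events(spec)
    out_dir = Path(out_dir)
    panels_dir = out_dir / "panels"
    clinvar_dir = out_dir / "clinvar"
    panels_dir.mkdir(parents=True, exist_ok=True)
    clinvar_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    months = spec.months()

    # -- gene universe ----------------------------------------------------
    gene_info: dict[str, tuple[str | None, int | None]] = {}
    state = _PanelState()
    for i in range(spec.n_genes):
        symbol = f"GENE{i:04d}"
        ensembl = f"ENSG{i:011d}"
        gene_info[symbol] = (ensembl, 1000 + i)
        u = rng.random()
        if u < spec.frac_diagnostic:
            rating = 3
        elif u < spec.frac_diagnostic + spec.frac_rating2:
            rating = 2
        else:
            rating = 1
        state.add(symbol, ensembl, rating)
    if spec.include_str_entry:
        state.add("STR_EXP1", None, 3, entity_type="str")
    extra_ncbi = [5000 + j for j in range(spec.n_extra_clinvar_genes)]

    # -- count series (baseline geometric growth, events applied in replay)
    all_ncbi = sorted(
        [n for _, n in gene_info.values() if n is not None] + extra_ncbi
    )
    n_tracked = len(all_ncbi)
    plp = np.zeros((n_tracked, spec.n_months), dtype=np.int64)
    benign = np.zeros_like(plp)
    plp[:, 0] = rng.integers(5, 120, size=n_tracked)
    benign[:, 0] = rng.integers(20, 300, size=n_tracked)
    for m in range(1, spec.n_months):
        g = np.clip(
            rng.normal(spec.monthly_growth, spec.growth_sd, size=n_tracked),
            0.0, spec.growth_cap,
        )
        plp[:, m] = np.rint(plp[:, m - 1] * (1.0 + g)).astype(np.int64)
        benign[:, m] = np.rint(benign[:, m - 1] * (1.0 + g)).astype(np.int64)
    ncbi_row = {n: i for i, n in enumerate(all_ncbi)}

    # -- replay events ----------------------------------------------------
    unmatched_ens: set[str] = set()
    clashes: dict[str, int] = {}  # ensembl -> decoy ncbi id
    log = EventLog()
    diag_symbols: dict[MonthKey, set[str]] = {spec.launch_month: state.diag_symbols()}
    versions: list[tuple[str, str, dict]] = []  # (version, filename stem, document)
    launch_ts = f"{spec.launch_month}-10T10:00:00+00:00"
    versions.append(("0.1", "v0.1", _panel_document(spec, state, "0.1", launch_ts)))

    taken: set[str] = set()
    n_new = 0
    version_counter = 1
    by_month: dict[MonthKey, list[Event]] = {}
    for ev in sorted(spec.events, key=lambda e: (e.month, e.kind, e.gene or "")):
        by_month.setdefault(ev.month, []).append(ev)

    for month in months[1:]:
        panel_changed = False
        for ev in by_month.get(month, []):
            entry: dict = {"month": str(month), "kind": ev.kind,
                           "magnitude": ev.magnitude}
            if ev.kind == "add_diag":
                n_new += 1
                symbol = ev.gene or f"NEWG{n_new:03d}"
                if symbol in state.entries:
                    raise ValueError(f"add_diag: {symbol} already on the panel")
                if symbol in gene_info:
                    ensembl, ncbi = gene_info[symbol]  # re-entry of a removed gene
                else:
                    ensembl = f"ENSG{90000 + n_new:011d}"
                    ncbi = 2000 + n_new
                    gene_info[symbol] = (ensembl, ncbi)
                    # the new gene gets a modest count series of its own
                    base_p = int(rng.integers(5, 60))
                    base_b = int(rng.integers(10, 150))
                    row = np.zeros(spec.n_months, dtype=np.int64)
                    rowb = np.zeros(spec.n_months, dtype=np.int64)
                    row[0], rowb[0] = base_p, base_b
                    for m in range(1, spec.n_months):
                        g = float(np.clip(rng.normal(spec.monthly_growth, spec.growth_sd),
                                          0.0, spec.growth_cap))
                        row[m] = round(row[m - 1] * (1.0 + g))
                        rowb[m] = round(rowb[m - 1] * (1.0 + g))
                    plp = np.vstack([plp, row])
                    benign = np.vstack([benign, rowb])
                    ncbi_row[ncbi] = plp.shape[0] - 1
                    all_ncbi.append(ncbi)
                state.add(symbol, ensembl, 3)
                panel_changed = True
            elif ev.kind == "upgrade":
                symbol = ev.gene or _pick(
                    state, lambda e: e["entity_type"] == "gene" and e["rating"] < 3,
                    taken, "upgrade")
                if state.entries[symbol]["rating"] >= 3:
                    raise ValueError(f"upgrade: {symbol} is already diagnostic")
                state.entries[symbol]["rating"] = 3
                panel_changed = True
            elif ev.kind == "downgrade":
                symbol = ev.gene or _pick(
                    state, lambda e: e["entity_type"] == "gene" and e["rating"] == 3,
                    taken, "downgrade")
                if state.entries[symbol]["rating"] != 3:
                    raise ValueError(f"downgrade: {symbol} is not diagnostic")
                state.entries[symbol]["rating"] = 2
                panel_changed = True
            elif ev.kind == "remove_diag":
                symbol = ev.gene or _pick(
                    state, lambda e: e["entity_type"] == "gene" and e["rating"] == 3,
                    taken, "remove_diag")
                if state.entries[symbol]["rating"] != 3:
                    raise ValueError(f"remove_diag: {symbol} is not diagnostic")
                del state.entries[symbol]
                panel_changed = True
            elif ev.kind in ("plp_step", "plp_decline"):
                # default to a diagnostic gene so the effect reaches the
                # joined diagnostic P/LP series
                symbol = ev.gene or _pick(
                    state,
                    lambda e: e["entity_type"] == "gene" and e["rating"] == 3
                    and e["ensembl"] is not None,
                    taken, ev.kind)
                ncbi = gene_info[symbol][1]
                if ncbi is None:
                    raise ValueError(f"{ev.kind}: {symbol} has no NCBI gene")
                mi = month.index - spec.launch_month.index
                delta = ev.magnitude if ev.kind == "plp_step" else -ev.magnitude
                r = ncbi_row[ncbi]
                floor = -int(plp[r, mi])
                delta = max(delta, floor)  # P/LP never negative
                plp[r, mi:] += delta
                entry["realised_delta"] = int(plp[r, mi] - plp[r, mi - 1])
            elif ev.kind == "unmatched_gene":
                symbol = ev.gene or _pick(
                    state,
                    lambda e: e["entity_type"] == "gene" and e["rating"] == 3
                    and e["ensembl"] is not None,
                    taken, "unmatched_gene")
                unmatched_ens.add(state.entries[symbol]["ensembl"])
            elif ev.kind == "id_clash":
                symbol = ev.gene or _pick(
                    state,
                    lambda e: e["entity_type"] == "gene" and e["rating"] == 3
                    and e["ensembl"] is not None,
                    taken, "id_clash")
                ensembl = state.entries[symbol]["ensembl"]
                decoy = 9000 + len(clashes)
                clashes[ensembl] = decoy
                # decoy gene: small, flat counts so largest-count picks the real one
                row = np.full(spec.n_months, 3, dtype=np.int64)
                rowb = np.full(spec.n_months, 5, dtype=np.int64)
                plp = np.vstack([plp, row])
                benign = np.vstack([benign, rowb])
                ncbi_row[decoy] = plp.shape[0] - 1
                all_ncbi.append(decoy)
                entry["decoy_ncbi"] = decoy
            taken.add(symbol)
            entry["symbol"] = symbol
            ensembl, ncbi = gene_info.get(symbol, (None, None))
            entry["ensembl_id"] = ensembl
            entry["ncbi_gene_id"] = ncbi
            log.entries.append(entry)
        if panel_changed:
            version_counter += 1
            version = f"0.{version_counter}"
            ts = f"{month}-15T10:00:00+00:00"
            versions.append((version, f"v{version}", _panel_document(spec, state, version, ts)))
        diag_symbols[month] = state.diag_symbols()

    # -- write panel versions ---------------------------------------------
    for _, stem, doc in versions:
        (panels_dir / f"{stem}.json").write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n"
        )

    # -- write monthly summary files --------------------------------------
    counts: dict[MonthKey, dict[int, tuple[int, int]]] = {}
    symbol_of = {n: s for s, (e, n) in gene_info.items() if n is not None}
    for decoy in clashes.values():
        symbol_of[decoy] = f"DECOY{decoy}"
    for n in extra_ncbi:
        symbol_of[n] = f"EXTRA{n}"
    header = ("#Symbol\tGeneID\tTotal_submissions\tTotal_alleles\t"
              "Alleles_reported_Pathogenic_Likely_pathogenic\tGene_MIM_number\n")
    for mi, month in enumerate(months):
        month_counts: dict[int, tuple[int, int]] = {}
        lines = [header]
        for ncbi in sorted(ncbi_row):
            r = ncbi_row[ncbi]
            p, t = int(plp[r, mi]), int(plp[r, mi] + benign[r, mi])
            month_counts[ncbi] = (t, p)
            lines.append(f"{symbol_of[ncbi]}\t{ncbi}\t{t}\t{t}\t{p}\t-\n")
        # aggregate row spanning genes, as in the real files; always skipped
        lines.append(f"GENE0000;GENE0001\t-1\t1\t1\t0\t-\n")
        (clinvar_dir / f"{month}.txt").write_text("".join(lines))
        counts[month] = month_counts

    # -- write mapping table ----------------------------------------------
    mapping_file = out_dir / "mapping.tsv"
    rows = ["NCBI gene ID\tGene stable ID\n"]
    for symbol in sorted(gene_info):
        ensembl, ncbi = gene_info[symbol]
        if ensembl is None or ncbi is None:
            continue
        if ensembl in unmatched_ens:
            rows.append(f"\t{ensembl}\n")  # one-sided: Ensembl with no NCBI match
            continue
        rows.append(f"{ncbi}\t{ensembl}\n")
        if ensembl in clashes:
            rows.append(f"{clashes[ensembl]}\t{ensembl}\n")
    for n in extra_ncbi:
        rows.append(f"{n}\t\n")  # one-sided: NCBI-only loci
    mapping_file.write_text("".join(rows))

    event_log_file = out_dir / "event_log.json"
    event_log_file.write_text(log.to_json() + "\n")

    return FixtureResult(
        spec=spec, out_dir=out_dir, panels_dir=panels_dir,
        clinvar_dir=clinvar_dir, mapping_file=mapping_file,
        event_log_file=event_log_file, event_log=log,
        gene_info=gene_info, diag_symbols=diag_symbols, counts=counts,
    )


def correlated_series(
    n: int, rho: float, seed: int, loc: float = 100.0, scale: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Two aligned series with planted population correlation ``rho``."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = [[1.0, rho], [rho, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return loc + scale * z[:, 0], loc + scale * z[:, 1]
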