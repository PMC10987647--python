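"""Change quantification: percent increases, monthly deltas, bursts, per-gene summaries.

All internal values stay unrounded floats; a separately named rounding step
(round half away from zero, to integer percent) is applied only when
formatting reports, so a display convention never leaks into arithmetic.
A percent change from a zero start is undefined and carried as ``None``
(never a division error); undefined months are excluded from summary
statistics with a warning count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .months import MonthKey
from .temporal_join import StaticGeneTable

__all__ = [
    "percentage_increase",
    "round_half_away",
    "format_percent",
    "ChangeSummary",
    "monthly_deltas",
    "BurstReport",
    "detect_bursts",
    "PerGeneChangeSummary",
    "per_gene_change_summary",
    "correlate",
]

logger = logging.getLogger(__name__)


def percentage_increase(start: float, end: float) -> float | None:
    """Percent change from ``start`` to ``end``: ``100 * (end - start) / start``.

    Returns ``None`` (undefined) when ``start`` is zero.
    """
    if start == 0:
        return None
    return 100.0 * (end - start) / start


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (reporting convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def format_percent(pct: float | None, mode: str = "round") -> str:
    """Format a percent for reports: ``round`` (half away) or ``truncate``."""
    if pct is None:
        return "NA"
    if mode == "truncate":
        return f"{int(pct)}%"
    return f"{round_half_away(pct)}%"


@dataclass
class ChangeSummary:
    """Endpoint and month-by-month change statistics for one count series."""

    start_month: MonthKey | None
    end_month: MonthKey | None
    start_value: int
    end_value: int
    absolute_increase: int
    percent_increase: float | None
    monthly_percent_changes: list[float | None] = field(default_factory=list)
    mean: float | None = None
    median: float | None = None
    min: float | None = None
    max: float | None = None
    n_undefined: int = 0

    @classmethod
    def from_endpoints(
        cls, start_value: int, end_value: int,
        start_month: MonthKey | None = None, end_month: MonthKey | None = None,
    ) -> "ChangeSummary":
        """Endpoint-only summary (no per-month series required)."""
        return cls(
            start_month=start_month, end_month=end_month,
            start_value=start_value, end_value=end_value,
            absolute_increase=end_value - start_value,
            percent_increase=percentage_increase(start_value, end_value),
        )

    def to_dict(self) -> dict:
        return {
            "window": [str(self.start_month), str(self.end_month)],
            "start_value": self.start_value,
            "end_value": self.end_value,
            "absolute_increase": self.absolute_increase,
            "percent_increase": self.percent_increase,
            "monthly_percent_changes": self.monthly_percent_changes,
            "mean": self.mean, "median": self.median,
            "min": self.min, "max": self.max,
            "n_undefined": self.n_undefined,
        }


def monthly_deltas(
    months: Sequence[MonthKey], values: Sequence[float]
) -> ChangeSummary:
    """Month-over-month percent changes plus endpoint summary for a series.

    The change attributed to month *m* is the percent increase from the
    value at *m-1* to the value at *m* (so the list has ``len - 1``
    entries, aligned with ``months[1:]``).  Months whose predecessor is
    zero are undefined and excluded from the mean/median/range.
    """
    if len(months) != len(values):
        raise ValueError("months and values must have equal length")
    if len(values) < 2:
        raise ValueError("monthly deltas need at least two months")
    changes: list[float | None] = [
        percentage_increase(values[i - 1], values[i]) for i in range(1, len(values))
    ]
    defined = [c for c in changes if c is not None]
    n_undef = len(changes) - len(defined)
    if n_undef:
        logger.warning("%d monthly changes undefined (zero predecessor)", n_undef)
    summary = ChangeSummary.from_endpoints(
        int(values[0]), int(values[-1]), months[0], months[-1]
    )
    summary.monthly_percent_changes = changes
    summary.n_undefined = n_undef
    if defined:
        summary.mean = float(np.mean(defined))
        summary.median = float(np.median(defined))
        summary.min = float(np.min(defined))
        summary.max = float(np.max(defined))
    return summary


@dataclass
class BurstReport:
    """Months whose percent change exceeds a threshold."""

    threshold_percent: float
    burst_months: list[tuple[MonthKey, float]]

    def month_keys(self) -> list[MonthKey]:
        return [m for m, _ in self.burst_months]

    def to_dict(self) -> dict:
        return {
            "threshold_percent": self.threshold_percent,
            "burst_months": [[str(m), c] for m, c in self.burst_months],
        }


def detect_bursts(
    months: Sequence[MonthKey],
    summary_or_changes: ChangeSummary | Sequence[float | None],
    threshold: float = 5.0,
    two_sided: bool = False,
) -> BurstReport:
    """Flag months whose percent change strictly exceeds ``threshold``.

    ``months`` are the series months; changes align with ``months[1:]``.
    With ``two_sided`` the magnitude is compared, catching large declines.
    """
    if isinstance(summary_or_changes, ChangeSummary):
        changes = summary_or_changes.monthly_percent_changes
    else:
        changes = list(summary_or_changes)
    if len(changes) != len(months) - 1:
        raise ValueError("changes must align with months[1:]")
    bursts = []
    for month, change in zip(months[1:], changes):
        if change is None:
            continue
        value = abs(change) if two_sided else change
        if value > threshold:
            bursts.append((month, change))
    return BurstReport(threshold, sorted(bursts))


@dataclass
class PerGeneChangeSummary:
    """Per-gene P/LP change over a window, plus cohort statistics and rankings."""

    start_month: MonthKey
    end_month: MonthKey
    per_gene: pd.DataFrame          # symbol, start_plp, end_plp, change
    excluded_symbols: list[str]     # missing at an endpoint
    mean: float
    median: float
    min: int
    max: int
    n_zero_change: int
    n_negative_change: int
    top_by_month: dict[MonthKey, list[tuple[str, int]]]  # top-k ranking

    def top_gene_every_month(self) -> str | None:
        """The symbol ranked first in every month, if a single one exists."""
        leaders = {ranks[0][0] for ranks in self.top_by_month.values() if ranks}
        return leaders.pop() if len(leaders) == 1 else None


def per_gene_change_summary(
    table: StaticGeneTable,
    start: MonthKey | None = None,
    end: MonthKey | None = None,
    top_k: int = 3,
) -> PerGeneChangeSummary:
    """Per-gene absolute P/LP change between window endpoints, with rankings.

    Genes missing at either endpoint are excluded from the change statistics
    and reported.  ``top_by_month`` ranks genes by P/LP count within each
    month of the window (descending count, symbol as tie-break).
    """
    start = start or table.months[0]
    end = end or table.months[-1]
    if start not in table.months or end not in table.months:
        raise ValueError(f"window {start}..{end} not covered by the table")

    df = table.frame
    at_start = df[(df["month"] == str(start)) & ~df["missing"]]
    at_end = df[(df["month"] == str(end)) & ~df["missing"]]
    merged = at_start[["symbol", "plp_alleles"]].merge(
        at_end[["symbol", "plp_alleles"]], on="symbol", suffixes=("_start", "_end")
    )
    merged["change"] = merged["plp_alleles_end"] - merged["plp_alleles_start"]
    all_symbols = set(df["symbol"].unique())
    excluded = sorted(all_symbols - set(merged["symbol"]))

    per_gene = merged.rename(
        columns={"plp_alleles_start": "start_plp", "plp_alleles_end": "end_plp"}
    )[["symbol", "start_plp", "end_plp", "change"]].sort_values(
        "change", ascending=False
    ).reset_index(drop=True)

    window = [m for m in table.months if start <= m <= end]
    top_by_month: dict[MonthKey, list[tuple[str, int]]] = {}
    for month in window:
        sub = df[(df["month"] == str(month)) & ~df["missing"]]
        ranked = sub.sort_values(
            ["plp_alleles", "symbol"], ascending=[False, True]
        ).head(top_k)
        top_by_month[month] = [
            (str(r.symbol), int(r.plp_alleles)) for r in ranked.itertuples(index=False)
        ]

    changes = per_gene["change"]
    return PerGeneChangeSummary(
        start_month=start, end_month=end, per_gene=per_gene,
        excluded_symbols=excluded,
        mean=float(changes.mean()), median=float(changes.median()),
        min=int(changes.min()), max=int(changes.max()),
        n_zero_change=int((changes == 0).sum()),
        n_negative_change=int((changes < 0).sum()),
        top_by_month=top_by_month,
    )


def correlate(series_a: Sequence[float], series_b: Sequence[float]) -> float | None:
    """Pearson product-moment correlation of two aligned series.

    Returns ``None`` for constant input (undefined), mirroring the
    undefined-marker convention used for zero-start percent changes.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must be aligned with length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)
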