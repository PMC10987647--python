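"""Calendar-month keys for monthly snapshot series.

Every time series in this package is indexed by calendar month: a panel has
one representative version per month, ClinVar publishes (roughly) one
gene-summary archive per month, and all joins happen month-by-month.
:class:`MonthKey` is the shared, totally ordered index type.
"""

from __future__ import annotations

import calendar
import re
from dataclasses import dataclass
from datetime import date, datetime, timezone

__all__ = ["MonthKey", "month_range"]

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


@dataclass(frozen=True, order=True)
class MonthKey:
    """A calendar month, totally ordered, with exact month arithmetic."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_date(cls, d: date | datetime) -> "MonthKey":
        return cls(d.year, d.month)

    @classmethod
    def parse(cls, text: str) -> "MonthKey":
        """Parse ``'YYYY-MM'``."""
        m = _MONTH_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse month key from {text!r} (want YYYY-MM)")
        return cls(int(m.group(1)), int(m.group(2)))

    # -- arithmetic -------------------------------------------------------
    @property
    def index(self) -> int:
        """Months since year 0; consecutive months differ by exactly 1."""
        return self.year * 12 + (self.month - 1)

    @classmethod
    def from_index(cls, idx: int) -> "MonthKey":
        return cls(idx // 12, idx % 12 + 1)

    def plus(self, n: int) -> "MonthKey":
        return MonthKey.from_index(self.index + n)

    def next(self) -> "MonthKey":
        return self.plus(1)

    def prev(self) -> "MonthKey":
        return self.plus(-1)

    # -- boundaries -------------------------------------------------------
    def last_day(self) -> date:
        return date(self.year, self.month, calendar.monthrange(self.year, self.month)[1])

    def end_instant(self, tz: timezone = timezone.utc) -> datetime:
        """23:59:59 on the last day of the month, in ``tz`` (UTC by default).

        This is the snapshot-selection cutoff: the panel version in force at
        this instant represents the month.
        """
        d = self.last_day()
        return datetime(d.year, d.month, d.day, 23, 59, 59, tzinfo=tz)

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start: MonthKey, end: MonthKey) -> list[MonthKey]:
    """All months from ``start`` to ``end`` inclusive."""
    if end < start:
        raise ValueError(f"month range end {end} precedes start {start}")
    return [MonthKey.from_index(i) for i in range(start.index, end.index + 1)]
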