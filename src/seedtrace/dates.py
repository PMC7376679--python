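"""Calendar dates with explicit precision.

Field files record dates either to the day or only to the year (a farmer
may remember the harvest year but not the day).  :class:`FlexDate` keeps
the original precision for display while giving every date a total order:
a year-only date sorts as July 1 of that year, mid-season for a northern
hemisphere cereal calendar.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

from .errors import DateParseError

_ISO_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_SLASH_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_YEAR_RE = re.compile(r"^(\d{4})$")


@dataclass(frozen=True, order=False)
class FlexDate:
    """A calendar date known either to the day or only to the year."""

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if (self.month is None) != (self.day is None):
            raise DateParseError("month and day must be given together")
        if self.month is not None:
            # delegate range validation to datetime
            _dt.date(self.year, self.month, self.day)

    @property
    def precision(self) -> str:
        return "year" if self.month is None else "day"

    def sort_key(self) -> _dt.date:
        """Total-order key: year-only dates pin to July 1."""
        if self.month is None:
            return _dt.date(self.year, 7, 1)
        return _dt.date(self.year, self.month, self.day)

    def __lt__(self, other: "FlexDate") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "FlexDate") -> bool:
        return self.sort_key() <= other.sort_key()

    def isoformat(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    def __str__(self) -> str:  # pragma: no cover - display sugar
        return self.isoformat()

    @classmethod
    def from_date(cls, d: _dt.date) -> "FlexDate":
        return cls(d.year, d.month, d.day)


def parse_date(text: str) -> FlexDate:
    """Parse ``YYYY-MM-DD``, day-first ``DD/MM/YYYY``, or bare ``YYYY``.

    The slash dialect is always day-first; ``04/07/2016`` is 4 July, never
    April 7.  Anything else — including month-first slash dates that have
    no day-first reading — raises :class:`DateParseError`.
    """
    if text is None:
        raise DateParseError("empty date")
    text = text.strip()
    if not text:
        raise DateParseError("empty date")
    m = _ISO_RE.match(text)
    if m:
        y, mo, d = (int(g) for g in m.groups())
        try:
            return FlexDate(y, mo, d)
        except ValueError as exc:
            raise DateParseError(f"invalid calendar date {text!r}") from exc
    m = _SLASH_RE.match(text)
    if m:
        d, mo, y = (int(g) for g in m.groups())
        try:
            return FlexDate(y, mo, d)
        except ValueError as exc:
            raise DateParseError(f"invalid day-first date {text!r}") from exc
    m = _YEAR_RE.match(text)
    if m:
        return FlexDate(int(m.group(1)))
    raise DateParseError(f"unrecognized date {text!r} (expect YYYY-MM-DD, DD/MM/YYYY or YYYY)")
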