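"""Calendar-month arithmetic on ISO "YYYY-MM" strings.

Claims payments are reported at month granularity; all pre/post windowing
is therefore done on integer month indices (year*12 + month-1), which keeps
window arithmetic exact and lexicographic string order consistent with
chronological order.
"""

from __future__ import annotations

import datetime as _dt
import re

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")
_DATE_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])-(0[1-9]|[12]\d|3[01])$")


def is_month(s: str) -> bool:
    return bool(_MONTH_RE.match(s))


def is_date(s: str) -> bool:
    return bool(_DATE_RE.match(s))


def month_index(month: str) -> int:
    """Map "YYYY-MM" to a consecutive integer index (Jan 0001 = 12)."""
    if not is_month(month):
        raise ValueError(f"not a YYYY-MM month: {month!r}")
    y, m = month.split("-")
    return int(y) * 12 + int(m) - 1


def month_str(index: int) -> str:
    return f"{index // 12:04d}-{index % 12 + 1:02d}"


def add_months(month: str, k: int) -> str:
    return month_str(month_index(month) + k)


def month_range(start: str, end: str) -> list[str]:
    """Inclusive list of months from start to end."""
    i, j = month_index(start), month_index(end)
    if j < i:
        raise ValueError(f"month range end {end} precedes start {start}")
    return [month_str(k) for k in range(i, j + 1)]


def month_of_date(date: str) -> str:
    if not is_date(date):
        raise ValueError(f"not a YYYY-MM-DD date: {date!r}")
    return date[:7]


def parse_date(date: str) -> _dt.date:
    if not is_date(date):
        raise ValueError(f"not a YYYY-MM-DD date: {date!r}")
    return _dt.date.fromisoformat(date)


def days_in_month(month: str) -> int:
    i = month_index(month) + 1
    first_next = _dt.date(i // 12, i % 12 + 1, 1)
    return (first_next - _dt.timedelta(days=1)).day


def date_str(d: _dt.date) -> str:
    return d.isoformat()
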