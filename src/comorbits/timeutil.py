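"""Calendar-month arithmetic.

Months are handled internally as integer indices (year * 12 + month - 1) so
that offsets between calendar months are plain integer differences.  Event
dates keep day-of-month resolution because the diagnosis-ascertainment rule
counts exact days between codes.
"""

from __future__ import annotations

import datetime as _dt

__all__ = [
    "month_to_int",
    "int_to_month",
    "parse_month",
    "date_month_int",
    "month_offset",
]


def month_to_int(year: int, month: int) -> int:
    """Map a (year, month) pair to a monotone integer month index."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year * 12 + (month - 1)


def int_to_month(m: int) -> str:
    """Inverse of :func:`month_to_int`, rendered as ISO ``yyyy-mm``."""
    year, month0 = divmod(m, 12)
    return f"{year:04d}-{month0 + 1:02d}"


def parse_month(label: str) -> int:
    """Parse an ISO ``yyyy-mm`` (or ``yyyy-mm-dd``) string to a month index."""
    parts = str(label).split("-")
    return month_to_int(int(parts[0]), int(parts[1]))


def date_month_int(d: _dt.date) -> int:
    return month_to_int(d.year, d.month)


def month_offset(d: _dt.date, index_month: int) -> int:
    """Whole-month offset of a date relative to an index month (index = 0)."""
    return date_month_int(d) - index_month
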