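"""Rendering conventions for descriptive tables.

Counts print with thousands separators; percentages follow the mixed
registry-table convention: whole percents at or above 10%, one decimal
between 0.05% and 10%, "<0.1%" below 0.05%, and a plain "0%" for true
zeros.  Centralized so that rendered tables are string-comparable.
"""

from __future__ import annotations


def format_percent(count: int, total: int) -> str:
    if total <= 0 or count == 0:
        return "0%"
    pct = 100.0 * count / total
    if pct < 0.05:
        return "<0.1%"
    if pct < 10:
        return f"{pct:.1f}%"
    return f"{pct:.0f}%"


def format_count(count: int) -> str:
    return f"{count:,}"


def format_cell(count: int, total: int) -> str:
    """E.g. ``1,251 (47%)``."""
    return f"{format_count(count)} ({format_percent(count, total)})"
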