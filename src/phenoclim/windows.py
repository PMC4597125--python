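"""Cyclic calendar-month windows.

A window is a run of consecutive calendar months, allowed to wrap the
year boundary (Nov-Jan is a valid length-3 window). Windows are written
``(start_month, length)`` with ``start_month`` in 1..12 and ``length``
in 1..12.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MonthWindow", "candidate_windows"]

MONTH_ABBR = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]


@dataclass(frozen=True, order=True)
class MonthWindow:
    start_month: int
    length: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= 12:
            raise ValueError(f"start_month {self.start_month} not in 1..12")
        if not 1 <= self.length <= 12:
            raise ValueError(f"length {self.length} not in 1..12")

    def months(self) -> tuple[int, ...]:
        """Calendar months covered, in cyclic order from the start."""
        return tuple((self.start_month - 1 + k) % 12 + 1 for k in range(self.length))

    def contains(self, month: int) -> bool:
        return (month - self.start_month) % 12 < self.length

    @property
    def end_month(self) -> int:
        return (self.start_month - 1 + self.length - 1) % 12 + 1

    @property
    def center_month(self) -> int:
        """Middle month (lower of the two middles for even lengths)."""
        return (self.start_month - 1 + (self.length - 1) // 2) % 12 + 1

    def label(self) -> str:
        if self.length == 1:
            return MONTH_ABBR[self.start_month - 1]
        return f"{MONTH_ABBR[self.start_month - 1]}-{MONTH_ABBR[self.end_month - 1]}"


def candidate_windows(window: MonthWindow) -> list[MonthWindow]:
    """All cyclic windows of the same length, the observed one first.

    For lengths up to 11 there are 12 distinct start months, i.e. the
    observed window plus 11 alternatives; a 12-month window has no
    distinct cyclic shift and is returned alone.
    """
    if window.length == 12:
        return [window]
    out = [window]
    for shift in range(1, 12):
        start = (window.start_month - 1 + shift) % 12 + 1
        out.append(MonthWindow(start, window.length))
    return out
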