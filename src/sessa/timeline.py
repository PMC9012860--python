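"""Per-patient exposure timelines as unions of half-open day intervals.

A timeline is the set of days on which a patient is considered exposed to
the drug: the union of ``[fill_day, fill_day + duration)`` intervals, one
per filled prescription.  All interval arithmetic is half-open — a fill on
day 0 with a 30-day supply covers days 0..29 and not day 30.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Tuple

import pandas as pd

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Merge half-open intervals into a disjoint, sorted tuple.

    Empty or inverted intervals (``end <= start``) are dropped.  Adjacent
    intervals (``[0, 30)`` and ``[30, 60)``) are coalesced.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class ExposureTimeline:
    """Union of half-open exposure intervals for one patient."""

    patient_id: str
    intervals: tuple[Interval, ...]

    @classmethod
    def from_intervals(cls, patient_id: str, intervals: Iterable[Interval]) -> "ExposureTimeline":
        return cls(patient_id=patient_id, intervals=merge_intervals(intervals))

    def is_exposed(self, day: int) -> bool:
        """True iff ``day`` lies inside some interval (half-open)."""
        starts = [s for s, _ in self.intervals]
        i = bisect_right(starts, day) - 1
        return i >= 0 and day < self.intervals[i][1]

    def covered_days(self, start: int, end: int) -> int:
        """Number of exposed days within the half-open window [start, end)."""
        total = 0
        for s, e in self.intervals:
            total += max(0, min(e, end) - max(s, start))
        return total

    @property
    def total_covered(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def exposed_days(self) -> Iterator[int]:
        """Iterate over every exposed day, ascending."""
        for s, e in self.intervals:
            yield from range(s, e)


def timelines_from_fills(
    fills: pd.DataFrame, duration_col: str, day_col: str = "day"
) -> dict[str, ExposureTimeline]:
    """Build one merged timeline per patient from a fills table.

    ``fills`` needs columns ``patient_id``, ``day_col`` and ``duration_col``
    (whole or fractional days; fractional durations are rounded half away
    from zero, matching end-of-supply semantics at daily resolution).
    """
    out: dict[str, ExposureTimeline] = {}
    for pid, sub in fills.groupby("patient_id", sort=True):
        ivs = [
            (int(d), int(d) + _round_half_away(length))
            for d, length in zip(sub[day_col], sub[duration_col])
            if pd.notna(length)
        ]
        out[str(pid)] = ExposureTimeline.from_intervals(str(pid), ivs)
    return out


def _round_half_away(x: float) -> int:
    """Round to the nearest whole day, halves away from zero."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def query_exposure(timelines: Mapping[str, ExposureTimeline], patient_id: str, day: int) -> bool:
    tl = timelines.get(patient_id)
    return tl.is_exposed(day) if tl is not None else False
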