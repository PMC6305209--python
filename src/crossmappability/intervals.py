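"""Half-open interval arithmetic on a single chromosome.

All intervals are 0-based, half-open ``[start, end)`` tuples of ints.
An :class:`IntervalSet` is kept sorted, disjoint and merged (abutting
intervals are coalesced), which makes union/subtraction/containment
unambiguous.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, Iterator, Sequence, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or abutting intervals; drop empty ones."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b; both inputs must be merged and sorted."""
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj][0] < e:
            bs, be = b[jj]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            jj += 1
        if cur < e:
            out.append((cur, e))
    return out


class IntervalSet:
    """Sorted, disjoint, merged half-open intervals on one chromosome."""

    __slots__ = ("_ivs", "_starts")

    def __init__(self, intervals: Iterable[Interval] = ()):
        self._ivs = merge_intervals(intervals)
        self._starts = [s for s, _ in self._ivs]

    @property
    def intervals(self) -> list[Interval]:
        return list(self._ivs)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._ivs)

    def __len__(self) -> int:
        return len(self._ivs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({self._ivs!r})"

    def total_length(self) -> int:
        return sum(e - s for s, e in self._ivs)

    def max_interval_length(self) -> int:
        return max((e - s for s, e in self._ivs), default=0)

    def contains(self, pos: int) -> bool:
        """True iff pos lies inside some interval (half-open)."""
        i = bisect_right(self._starts, pos) - 1
        return i >= 0 and pos < self._ivs[i][1]

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self._ivs + other._ivs)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(subtract_intervals(self._ivs, other._ivs))

    def span(self) -> Interval:
        if not self._ivs:
            raise ValueError("empty interval set has no span")
        return (self._ivs[0][0], self._ivs[-1][1])
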