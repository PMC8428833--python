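"""Half-open integer interval arithmetic.

All coordinates throughout the package are 0-based half-open ``(start, end)``
pairs in base pairs. These helpers are the workhorse behind breadth-of-coverage
computation, unaligned-fragment excision and deletion/gene overlap tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge possibly-overlapping intervals into a disjoint list.

    Adjacent intervals (end == next start) are coalesced; empty intervals
    are dropped.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            if e > le:
                out[-1] = (ls, e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlap length between two sorted disjoint interval lists."""
    i = j = 0
    out = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement(intervals: Sequence[Interval], length: int) -> list[Interval]:
    """Gaps of ``[0, length)`` not covered by the (sorted, disjoint) intervals."""
    out: list[Interval] = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


class IntervalIndex:
    """Sorted-array interval set supporting fast covered-length queries.

    Built once per (accession, sequence); ``covered_length`` then answers
    breadth queries for gene bodies and CDS unions in O(log n + k).
    """

    __slots__ = ("starts", "ends")

    def __init__(self, intervals: Sequence[Interval]):
        ivs = merge_intervals(intervals)
        self.starts = np.fromiter((s for s, _ in ivs), dtype=np.int64, count=len(ivs))
        self.ends = np.fromiter((e for _, e in ivs), dtype=np.int64, count=len(ivs))

    def covered_length(self, region: Sequence[Interval]) -> int:
        """Number of positions of ``region`` (disjoint intervals) covered."""
        if len(self.starts) == 0:
            return 0
        out = 0
        for rs, re in region:
            lo = int(np.searchsorted(self.ends, rs, side="right"))
            hi = int(np.searchsorted(self.starts, re, side="left"))
            for k in range(lo, hi):
                s = max(int(self.starts[k]), rs)
                e = min(int(self.ends[k]), re)
                if e > s:
                    out += e - s
        return out

    def to_intervals(self) -> list[Interval]:
        return [(int(s), int(e)) for s, e in zip(self.starts, self.ends)]
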