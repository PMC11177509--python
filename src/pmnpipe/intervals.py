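"""1-based closed-interval arithmetic shared by the calling and MCR stages."""

from __future__ import annotations

__all__ = ["overlap_len", "merge_intervals", "intersect_many", "total_len"]

Interval = tuple[int, int]


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Number of bases shared by two 1-based closed intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Coalesce overlapping or bookended (end+1 == start) closed intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def intersect_many(interval_sets: list[list[Interval]]) -> list[Interval]:
    """Maximal intervals covered by every one of the given merged interval sets.

    Sweep-line over interval endpoints: a base is in the result iff its
    support count equals the number of sets.
    """
    n = len(interval_sets)
    if n == 0:
        return []
    events: list[tuple[int, int]] = []  # (position, +1/-1); closed intervals
    for ivs in interval_sets:
        for s, e in ivs:
            events.append((s, 1))
            events.append((e + 1, -1))
    events.sort()
    out: list[Interval] = []
    depth = 0
    open_start: int | None = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth == n and open_start is None:
            open_start = pos
        elif depth < n and open_start is not None:
            out.append((open_start, pos - 1))
            open_start = None
    return out


def total_len(intervals: list[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)
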