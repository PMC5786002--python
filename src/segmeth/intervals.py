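"""Half-open interval arithmetic on (start, end) pairs.

All coordinates are 0-based, half-open (BED convention). Inputs need not be
sorted; outputs are sorted by start. These helpers are deliberately free of
any genomic typing so every module can share them.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge(intervals: Iterable[tuple[int, int]], book_ended: bool = True) -> list[tuple[int, int]]:
    """Merge overlapping (and, by default, book-ended) intervals.

    Parameters
    ----------
    intervals
        Iterable of (start, end) with start < end.
    book_ended
        If True, [0, 10) and [10, 20) merge into [0, 20).
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        joins = s <= out[-1][1] if book_ended else s < out[-1][1]
        if joins:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference a \\ b. Both sides are merged internally first."""
    a = merge(a)
    b = merge(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set intersection of two interval sets."""
    a = merge(a)
    b = merge(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge(intervals))


def complement(intervals: Sequence[tuple[int, int]], span: tuple[int, int]) -> list[tuple[int, int]]:
    """Complement of the interval set within span=[lo, hi)."""
    return subtract([span], intervals)


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Overlap in bp between two single intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def gap_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Distance between two intervals; 0 if they overlap or touch."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard index (bp overlap / bp union) of two intervals."""
    inter = overlap_length(a, b)
    if inter == 0:
        return 0.0
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union
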