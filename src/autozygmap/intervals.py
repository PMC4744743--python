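"""Set operations on 1-based inclusive genomic intervals (single chromosome).

Intervals are ``(start, end)`` integer pairs with ``start <= end``.  All
functions return merged, sorted, non-overlapping lists.  These are used on
per-sample autozygous-region lists, which are small (rarely more than a few
dozen per genome).
"""

from __future__ import annotations


def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of a list of intervals; adjacent intervals (gap 0) are joined."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s > e:
            raise ValueError(f"interval start {s} > end {e}")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two interval unions."""
    a, b = merge(a), merge(b)
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets: list[list[tuple[int, int]]]) -> list[tuple[int, int]]:
    if not sets:
        return []
    acc = merge(sets[0])
    for nxt in sets[1:]:
        acc = intersect(acc, nxt)
        if not acc:
            break
    return acc


def subtract(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intervals of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    return out


def total_length(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by an interval union."""
    return sum(e - s + 1 for s, e in merge(intervals))


def contains(intervals: list[tuple[int, int]], pos: int) -> bool:
    """1-based inclusive containment test (linear scan; lists are tiny)."""
    return any(s <= pos <= e for s, e in intervals)
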