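"""Interval arithmetic on 0-based half-open intervals.

These primitives drive the align-and-subtract loop: the union of aligned
query intervals is taken per read, and its complement yields the unmapped
fragments.
"""

from __future__ import annotations

from .io import Interval

__all__ = ["merge_intervals", "complement_intervals", "total_length"]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/touching runs merged."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out = [Interval(ivs[0].start, ivs[0].end)]
    for iv in ivs[1:]:
        if iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(Interval(iv.start, iv.end))
    return out


def complement_intervals(merged: list[Interval], length: int) -> list[Interval]:
    """Gaps of [0, length) not covered by ``merged`` (sorted, disjoint)."""
    out = []
    cursor = 0
    for iv in merged:
        if iv.end > length:
            raise ValueError(f"interval [{iv.start},{iv.end}) exceeds length {length}")
        if iv.start > cursor:
            out.append(Interval(cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < length:
        out.append(Interval(cursor, length))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(len(iv) for iv in intervals)
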