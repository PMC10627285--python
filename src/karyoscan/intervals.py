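"""Exact interval algebra: merge, intersect, subtract, zero-overlap filter.

The b-side of every binary operation is merged first so that overlapping
annotations (common in repeat libraries) never produce double-counted
output; this makes length(intersect) + length(subtract) == length(merge(a))
hold exactly for self-nonoverlapping a.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval

__all__ = [
    "merge_intervals",
    "total_length",
    "interval_overlap",
]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per sequence, sorted; names/strands are dropped."""
    by_seq: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_seq[iv.seq_id].append(iv)
    out: list[GenomicInterval] = []
    for seq_id in sorted(by_seq):
        ivs = sorted(by_seq[seq_id], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(seq_id, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(seq_id, cur_start, cur_end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def _trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.seq_id].addi(iv.start, iv.end)
    return trees


def interval_overlap(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    mode: str = "intersect",
) -> list[GenomicInterval]:
    """Overlap algebra between two interval sets on a shared namespace.

    intersect
        Sub-intervals of each a member covered by the union of b.
    subtract
        Parts of each a member not covered by the union of b.
    nonoverlapping_a
        Members of a with zero overlap with b (the selector used to pick
        genes lying entirely within nonrepetitive sequence).
    """
    if mode not in ("intersect", "subtract", "nonoverlapping_a"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    b_merged = merge_intervals(set_b) if set_b else []
    trees = _trees(b_merged)
    out: list[GenomicInterval] = []
    for a in set_a:
        tree = trees.get(a.seq_id)
        hits = sorted(tree.overlap(a.start, a.end)) if tree is not None else []
        if mode == "nonoverlapping_a":
            if not hits:
                out.append(a)
            continue
        if mode == "intersect":
            for h in hits:
                out.append(
                    GenomicInterval(
                        a.seq_id, max(a.start, h.begin), min(a.end, h.end),
                        a.strand, a.name, a.kind,
                    )
                )
            continue
        # subtract: walk the merged b cover left to right
        cursor = a.start
        for h in hits:
            if h.begin > cursor:
                out.append(
                    GenomicInterval(a.seq_id, cursor, h.begin, a.strand, a.name, a.kind)
                )
            cursor = max(cursor, h.end)
        if cursor < a.end:
            out.append(GenomicInterval(a.seq_id, cursor, a.end, a.strand, a.name, a.kind))
    return out


def overlap_length(a: GenomicInterval, intervals: Sequence[GenomicInterval]) -> int:
    """Total bases of ``a`` covered by the union of ``intervals``."""
    merged = merge_intervals([iv for iv in intervals if iv.seq_id == a.seq_id])
    covered = 0
    for m in merged:
        covered += max(0, min(a.end, m.end) - max(a.start, m.start))
    return covered
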