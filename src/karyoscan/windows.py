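"""Windowed GC-content and repeat-density profiles, and enriched-region calls.

Profiles tile each sequence with fixed windows (the trailing partial
window is emitted with its true length, so density x length sums exactly
to the total masked length).  Enriched-region calling finds runs of
windows above a threshold and classifies them as lying in the central or
terminal third of the chromosome -- the signature used to flag
centromere-candidate repeat concentrations.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval, SequenceRecord
from .intervals import merge_intervals

__all__ = [
    "WindowProfile",
    "EnrichedRegion",
    "gc_profile",
    "repeat_density",
    "call_enriched_regions",
]


@dataclass
class WindowProfile:
    seq_id: str
    window_start: int
    window_end: int
    metric: str
    value: float  # nan when undefined (e.g. an all-N window for GC)
    effective_length: int


@dataclass
class EnrichedRegion:
    seq_id: str
    span: GenomicInterval
    metric: str
    peak_value: float
    location_class: str  # center_third | terminal_third


def _window_bounds(length: int, window: int, step: int):
    start = 0
    while start < length:
        yield start, min(start + window, length)
        start += step


def gc_profile(
    seq: SequenceRecord, window: int = 50_000, step: int = 50_000
) -> list[WindowProfile]:
    """Per-window GC fraction: (G+C)/(A+C+G+T).

    N bases are excluded from the denominator; a window with no
    unambiguous base gets value nan.  The trailing partial window is
    emitted with its true effective length.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if len(seq.seq) == 0:
        raise ValueError(f"empty sequence {seq.id!r}")
    arr = np.frombuffer(seq.seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    acgt_cum = np.concatenate([[0], np.cumsum(is_acgt)])
    out = []
    for w_start, w_end in _window_bounds(len(arr), window, step):
        eff = int(acgt_cum[w_end] - acgt_cum[w_start])
        gc = int(gc_cum[w_end] - gc_cum[w_start])
        value = gc / eff if eff else math.nan
        out.append(WindowProfile(seq.id, w_start, w_end, "gc_fraction", value, eff))
    return out


def repeat_density(
    mask: Sequence[GenomicInterval],
    seq_lengths: Mapping[str, int],
    window: int = 50_000,
    class_or_family_filter: str | None = None,
) -> list[WindowProfile]:
    """Fraction of each window covered by (merged) mask intervals.

    ``class_or_family_filter`` keeps only mask intervals whose name or
    ``repeat_class``/``family`` attribute equals the filter, so the same
    repeat annotation can be profiled per class (e.g. LINE in 5-kb
    windows, LTR in 50-kb windows).
    """
    if class_or_family_filter is not None:
        mask = [
            iv
            for iv in mask
            if class_or_family_filter
            in (iv.name, iv.attrs.get("repeat_class"), iv.attrs.get("family"))
        ]
    metric = f"masked_fraction({class_or_family_filter or 'all'})"
    by_seq: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in mask:
        if iv.seq_id not in seq_lengths:
            raise ValueError(f"mask interval on unknown sequence {iv.seq_id!r}")
        if iv.end > seq_lengths[iv.seq_id]:
            raise ValueError(
                f"mask interval {iv.seq_id}:{iv.start}-{iv.end} exceeds sequence "
                f"length {seq_lengths[iv.seq_id]}"
            )
        by_seq[iv.seq_id].append(iv)
    out = []
    for seq_id in seq_lengths:
        length = seq_lengths[seq_id]
        merged = merge_intervals(by_seq.get(seq_id, []))
        starts = np.array([m.start for m in merged], dtype=np.int64)
        ends = np.array([m.end for m in merged], dtype=np.int64)
        for w_start, w_end in _window_bounds(length, window, window):
            if len(starts):
                covered = int(
                    np.clip(np.minimum(ends, w_end) - np.maximum(starts, w_start), 0, None).sum()
                )
            else:
                covered = 0
            w_len = w_end - w_start
            out.append(
                WindowProfile(seq_id, w_start, w_end, metric, covered / w_len, w_len)
            )
    return out


def call_enriched_regions(
    profile: Sequence[WindowProfile],
    threshold: float = 0.5,
    min_windows: int = 1,
    seq_lengths: Mapping[str, int] | None = None,
) -> list[EnrichedRegion]:
    """Maximal runs of >= min_windows consecutive windows with value > threshold.

    The run is classified ``center_third`` when its midpoint falls in the
    middle third of the chromosome, else ``terminal_third``.  Chromosome
    length is taken from ``seq_lengths`` or, failing that, from the last
    window end of the profile (windows tile the whole sequence).
    """
    metrics = {p.metric for p in profile}
    if len(metrics) > 1:
        raise ValueError(f"profile mixes metrics {sorted(metrics)}")
    by_seq: dict[str, list[WindowProfile]] = defaultdict(list)
    for p in profile:
        by_seq[p.seq_id].append(p)
    out: list[EnrichedRegion] = []
    for seq_id, wins in by_seq.items():
        wins.sort(key=lambda p: p.window_start)
        length = (seq_lengths or {}).get(seq_id, wins[-1].window_end)
        run: list[WindowProfile] = []

        def _flush():
            if len(run) < min_windows:
                return
            span = GenomicInterval(
                seq_id, run[0].window_start, run[-1].window_end, kind="window"
            )
            mid = (span.start + span.end) / 2
            loc = (
                "center_third"
                if length / 3 <= mid < 2 * length / 3
                else "terminal_third"
            )
            out.append(
                EnrichedRegion(
                    seq_id, span, run[0].metric,
                    max(p.value for p in run), loc,
                )
            )

        for p in wins:
            if not math.isnan(p.value) and p.value > threshold:
                run.append(p)
            else:
                _flush()
                run = []
        _flush()
    return out


def profiles_to_rows(profile: Iterable[WindowProfile]) -> list[tuple]:
    """Long-format rows (seq_id, start, end, metric, value) for TSV export."""
    return [
        (p.seq_id, p.window_start, p.window_end, p.metric, p.value) for p in profile
    ]
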