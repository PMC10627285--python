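"""Telomeric tandem-repeat detection at contig ends.

Fungal chromosomes are capped by tandem arrays of a short unit, here
CCCTAA by default (its reverse complement TTAGGG appears at the 3' end).
An array is accepted when at least ``min_copies`` tandem copies of the
unit (or its reverse complement) occur with overall mismatch fraction at
most ``max_mismatch_fraction``, starting within ``end_window`` bases of a
contig terminus.  The maximal such array per end is reported.

Array semantics (shared with the brute-force oracle used in testing):
an array is a pair (s, t) -- start position and total length in bases --
with t >= min_copies * |unit|; its mismatch count is the Hamming distance
between seq[s:s+t] and the unit tiled to length t (N counts as a
mismatch); it is valid when mismatches / t <= max_mismatch_fraction.
Among valid arrays anchored at an end, the one with the largest t wins,
ties broken by fewer mismatches, then by start closest to the terminus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import DNA_ALPHABET, GenomicInterval, SequenceRecord, revcomp

__all__ = [
    "TelomereScanConfig",
    "TelomereHit",
    "scan_telomeres",
    "classify_chromosome_ends",
]


@dataclass
class TelomereScanConfig:
    unit: str = "CCCTAA"
    min_copies: float = 5.0
    max_mismatch_fraction: float = 0.1
    end_window: int = 1000
    max_array_length: int = 20000  # longest array considered, in bases

    def __post_init__(self) -> None:
        self.unit = self.unit.upper()
        if len(self.unit) < 2:
            raise ValueError("telomere unit must be at least 2 bases")
        if set(self.unit) - (DNA_ALPHABET - {"N"}):
            raise ValueError(f"telomere unit {self.unit!r} contains non-ACGT characters")
        if self.min_copies < 1:
            raise ValueError("min_copies must be >= 1")
        if not 0 <= self.max_mismatch_fraction < 1:
            raise ValueError("max_mismatch_fraction must be in [0, 1)")


@dataclass
class TelomereHit:
    seq_id: str
    contig_end: str  # five_prime | three_prime
    span: GenomicInterval
    unit: str
    copies: float
    strand: str
    mismatches: int


def _mismatch_cumsums(region: np.ndarray, unit: str) -> np.ndarray:
    """Cumulative mismatch counts of ``region`` against the unit tiled at
    every phase.  Row p, column i: mismatches of region[:i] against the
    tiling that would align a unit start at any position s with s % u == p.
    """
    u = len(unit)
    n = len(region)
    unit_arr = np.frombuffer(unit.encode(), dtype=np.uint8)
    idx = np.arange(n)
    cums = np.empty((u, n + 1), dtype=np.int64)
    for p in range(u):
        ref = unit_arr[(idx - p) % u]
        mism = (region != ref).astype(np.int64)
        cums[p, 0] = 0
        np.cumsum(mism, out=cums[p, 1:])
    return cums


def _best_array_at_start(
    seq: str, unit: str, config: TelomereScanConfig
) -> tuple[int, int, int] | None:
    """Maximal valid array anchored within end_window of the 5' end of
    ``seq`` for one unit orientation.  Returns (start, length, mismatches)
    or None."""
    u = len(unit)
    min_len = int(np.ceil(config.min_copies * u))
    region_len = min(len(seq), config.end_window + config.max_array_length)
    region = np.frombuffer(seq[:region_len].encode(), dtype=np.uint8)
    cums = _mismatch_cumsums(region, unit)
    max_mm = config.max_mismatch_fraction

    best = None  # (-length, mismatches, start)
    n_starts = min(config.end_window, max(0, region_len - min_len + 1))
    t_axis = None
    for s in range(n_starts):
        c = cums[s % u]
        t_max = min(region_len - s, config.max_array_length)
        if t_max < min_len:
            break
        if t_axis is None or len(t_axis) != t_max:
            t_axis = np.arange(1, t_max + 1)
        mm = c[s + 1 : s + t_max + 1] - c[s]
        valid = mm <= max_mm * t_axis
        valid[: min_len - 1] = False
        if not valid.any():
            continue
        t_best = int(np.nonzero(valid)[0][-1]) + 1
        cand = (-t_best, int(mm[t_best - 1]), s)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    neg_t, mism, s = best
    return s, -neg_t, mism


def _scan_five_prime(rec_id: str, seq: str, config: TelomereScanConfig, units: dict):
    """Best array anchored at the 5' end, over both unit orientations."""
    best = None
    for strand, unit in units.items():
        res = _best_array_at_start(seq, unit, config)
        if res is None:
            continue
        s, t, mism = res
        cand = (-t, mism, s, strand)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    neg_t, mism, s, strand = best
    t = -neg_t
    u = len(config.unit)
    return TelomereHit(
        seq_id=rec_id,
        contig_end="five_prime",
        span=GenomicInterval(rec_id, s, s + t, strand, kind="telomere", name=f"{rec_id}_5p"),
        unit=config.unit,
        copies=round(t / u, 1),
        strand=strand,
        mismatches=mism,
    )


def scan_telomeres(
    assembly: Sequence[SequenceRecord], config: TelomereScanConfig | None = None
) -> list[TelomereHit]:
    """Scan every contig end for a telomeric tandem array.

    At most one hit is reported per end (the maximal array).  The 3' end
    is scanned by applying the 5' scanner to the reverse complement and
    mapping coordinates back, which guarantees strict reverse-complement
    symmetry of the detector.
    """
    if not assembly:
        raise ValueError("empty assembly")
    config = config or TelomereScanConfig()
    units = {"+": config.unit, "-": revcomp(config.unit)}
    hits: list[TelomereHit] = []
    for rec in assembly:
        five = _scan_five_prime(rec.id, rec.seq, config, units)
        if five is not None:
            hits.append(five)
        rc_hit = _scan_five_prime(rec.id, revcomp(rec.seq), config, units)
        if rc_hit is not None:
            L = len(rec.seq)
            span = rc_hit.span
            flipped = "-" if rc_hit.strand == "+" else "+"
            hits.append(
                TelomereHit(
                    seq_id=rec.id,
                    contig_end="three_prime",
                    span=GenomicInterval(
                        rec.id, L - span.end, L - span.start, flipped,
                        kind="telomere", name=f"{rec.id}_3p",
                    ),
                    unit=config.unit,
                    copies=rc_hit.copies,
                    strand=flipped,
                    mismatches=rc_hit.mismatches,
                )
            )
    return hits


def classify_chromosome_ends(
    hits: Iterable[TelomereHit], assembly: Sequence[SequenceRecord]
) -> tuple[dict[str, str], Counter]:
    """Label every sequence by telomere completeness.

    Returns (labels, summary) where labels maps seq_id to one of
    ``both``, ``five_prime_only``, ``three_prime_only``, ``none`` and
    summary counts sequences per label.
    """
    known = {rec.id for rec in assembly}
    ends: dict[str, set[str]] = {rec.id: set() for rec in assembly}
    for hit in hits:
        if hit.seq_id not in known:
            raise ValueError(f"hit references unknown sequence {hit.seq_id!r}")
        ends[hit.seq_id].add(hit.contig_end)
    labels = {}
    for seq_id, found in ends.items():
        if found == {"five_prime", "three_prime"}:
            labels[seq_id] = "both"
        elif found == {"five_prime"}:
            labels[seq_id] = "five_prime_only"
        elif found == {"three_prime"}:
            labels[seq_id] = "three_prime_only"
        else:
            labels[seq_id] = "none"
    return labels, Counter(labels.values())
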