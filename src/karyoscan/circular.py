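"""Terminal-overlap detection and trimming for linearized circular contigs.

An assembler that walks a circular molecule (typically an organelle
genome) past its origin emits a linear contig whose prefix duplicates
its suffix.  ``detect_terminal_overlap`` finds the maximal prefix length
L >= min_overlap whose match against the length-L suffix reaches
``min_identity``, and returns the contig with the suffix copy removed.
Trimming is idempotent: rerunning the detector on the trimmed sequence
finds no overlap, which ``verify_circularity`` checks (also after
rotating the sequence, since a circle has no distinguished origin).

For exact matching (min_identity = 1.0) the overlap is the longest
border of the contig, computed with the KMP prefix function in O(n); a
quadratic scan over all candidate lengths serves as the independent test
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SequenceRecord

__all__ = ["OverlapResult", "detect_terminal_overlap", "verify_circularity"]


@dataclass
class OverlapResult:
    input_length: int
    overlap_length: int  # 0 when no qualifying overlap
    identity: float
    trimmed_length: int
    trimmed_seq: SequenceRecord


def _prefix_function(s: str) -> list[int]:
    pi = [0] * len(s)
    k = 0
    for i in range(1, len(s)):
        while k and s[i] != s[k]:
            k = pi[k - 1]
        if s[i] == s[k]:
            k += 1
        pi[i] = k
    return pi


def _borders(s: str) -> list[int]:
    """All border lengths of s (prefix == suffix), longest first."""
    pi = _prefix_function(s)
    out = []
    k = pi[-1] if pi else 0
    while k:
        out.append(k)
        k = pi[k - 1]
    return out


def detect_terminal_overlap(
    contig: SequenceRecord, min_overlap: int = 1000, min_identity: float = 1.0
) -> OverlapResult:
    """Find and trim the maximal terminal duplication of a contig.

    Returns overlap_length 0 (and the contig unchanged) when no prefix of
    length >= min_overlap matches the corresponding suffix at
    >= min_identity.  With min_identity < 1 the largest qualifying length
    is taken; identity is fraction of matching positions (N never
    matches).
    """
    n = len(contig.seq)
    if not 0 < min_overlap < n / 2:
        raise ValueError(
            f"contig length {n} must exceed 2 x min_overlap ({min_overlap})"
        )
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")

    best_len = 0
    best_identity = 0.0
    if min_identity >= 1.0:
        for L in _borders(contig.seq):
            if L >= min_overlap:
                best_len, best_identity = L, 1.0
                break
    else:
        seq = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
        is_n = seq == ord("N")
        for L in range(n - 1, min_overlap - 1, -1):
            matches = int(
                ((seq[:L] == seq[n - L :]) & ~is_n[:L] & ~is_n[n - L :]).sum()
            )
            identity = matches / L
            if identity >= min_identity:
                best_len, best_identity = L, identity
                break

    if best_len == 0:
        return OverlapResult(n, 0, 0.0, n, contig)
    trimmed = SequenceRecord(contig.id, contig.seq[: n - best_len], contig.description)
    return OverlapResult(n, best_len, best_identity, n - best_len, trimmed)


def verify_circularity(
    trimmed: SequenceRecord, k: int = 500, min_overlap: int = 1000
) -> bool:
    """True iff trimming was complete: neither the trimmed sequence nor a
    rotation of it by ``k`` retains a terminal overlap."""
    n = len(trimmed.seq)
    if not 0 < k < n / 2:
        raise ValueError(f"rotation k={k} must be in (0, length/2)")
    if detect_terminal_overlap(trimmed, min_overlap).overlap_length:
        return False
    rotated = SequenceRecord(trimmed.id, trimmed.seq[k:] + trimmed.seq[:k])
    return detect_terminal_overlap(rotated, min_overlap).overlap_length == 0
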