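"""Core domain types shared by every stage of the toolkit.

Coordinates are 0-based half-open everywhere inside the package; GFF3 and
other 1-based formats are converted at the I/O boundary.  Alignment hits
keep the 1-based inclusive convention of blast-style tabular output, with
``t_start > t_end`` encoding a minus-strand hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

__all__ = [
    "DNA_ALPHABET",
    "SequenceRecord",
    "GenomicInterval",
    "HitRecord",
    "revcomp",
    "gc_fraction",
    "percent",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T; N bases are excluded from the denominator.

    Returns ``nan`` for a sequence with no unambiguous base.
    """
    g = seq.count("G") + seq.count("g")
    c = seq.count("C") + seq.count("c")
    a = seq.count("A") + seq.count("a")
    t = seq.count("T") + seq.count("t")
    denom = a + c + g + t
    if denom == 0:
        return math.nan
    return (g + c) / denom


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-away-from-zero to ``decimals`` places.

    This is the rounding convention of the summary tables the package
    emits (e.g. 9239/11060 -> 83.54).  Python's builtin ``round`` uses
    banker's rounding, which differs on exact halves, hence Decimal.
    """
    if denominator == 0:
        raise ValueError("percentage of an empty total is undefined")
    q = Decimal(numerator) / Decimal(denominator) * 100
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def _check_token(value: str, what: str) -> None:
    if not value or any(ch.isspace() for ch in value):
        raise ValueError(f"{what} must be a nonempty whitespace-free token, got {value!r}")


@dataclass
class SequenceRecord:
    """A named DNA sequence (contig, chromosome, or simulated molecule)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        _check_token(self.id, "sequence id")
        self.seq = self.seq.upper()
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.seq), self.description)


VALID_STRANDS = ("+", "-", ".")
VALID_KINDS = ("gene", "repeat", "window", "telomere", "other")


@dataclass
class GenomicInterval:
    """A located feature with 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    kind: str = "other"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_token(self.seq_id, "interval seq_id")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"invalid interval kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class HitRecord:
    """One translated-search alignment between a protein query and a genome.

    Coordinates are 1-based inclusive (blast tabular convention);
    ``t_start > t_end`` encodes a minus-strand hit.
    """

    query_id: str
    target_seq: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    pct_identity: float
    pct_similarity: float
    aln_len: int
    bit_score: float
    e_value: float
    frame: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pct_identity <= self.pct_similarity <= 100):
            raise ValueError(
                "need 0 <= pct_identity <= pct_similarity <= 100, got "
                f"{self.pct_identity}/{self.pct_similarity}"
            )
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if self.e_value < 0:
            raise ValueError("E-value must be nonnegative")

    @property
    def strand(self) -> str:
        return "-" if self.t_start > self.t_end else "+"

    @property
    def t_low(self) -> int:
        """Lowest 1-based target coordinate regardless of strand."""
        return min(self.t_start, self.t_end)
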