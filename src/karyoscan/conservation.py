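"""Cross-assembly gene conservation via translated protein-to-genome search.

Each predicted protein is aligned locally (Smith-Waterman, affine gaps,
BLOSUM62 by default) against all six reading frames of the target
genome -- a desk-scale equivalent of a TBLASTN search, without heuristic
seeding.  E-values follow the Karlin-Altschul form E = K m n e^(-lambda S);
they act as a reporting threshold (default 1.0e-10), so the published
ungapped BLOSUM62 constants are adequate and configurable.

Genes are then partitioned three ways against the other assembly:

``unique``          no hit at E <= cutoff;
``low_similarity``  best hit below the identity (or similarity) threshold,
                    50% by default;
``common``          everything else.

The best hit is the one with the highest bit score, ties broken by lower
E-value, then by lower target coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core import HitRecord, SequenceRecord, percent, revcomp

__all__ = [
    "TranslatedSearchConfig",
    "ConservationCall",
    "ConservationSummary",
    "six_frame_translate",
    "translated_search",
    "best_hit",
    "classify_conservation",
    "summarize_conservation",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass
class TranslatedSearchConfig:
    scoring_matrix: str = "BLOSUM62"
    gap_open: int = 11  # cost of opening a gap (a gap of length k costs open + k*extend)
    gap_extend: int = 1
    evalue_cutoff: float = 1.0e-10
    karlin_lambda: float = 0.3176  # published ungapped BLOSUM62 constants
    karlin_k: float = 0.134
    search_space: float | None = None  # m*n override; default query_aa x db_nt

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")

    def aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.scoring_matrix)
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class ConservationCall:
    gene_id: str
    conservation_class: str  # common | low_similarity | unique
    best_hit: HitRecord | None
    criterion_value: float | None  # % identity or similarity backing the call


@dataclass
class ConservationSummary:
    counts: dict
    percentages: dict
    total: int


def six_frame_translate(seq: str) -> list[tuple[int, str]]:
    """Translate a DNA string in all six frames.

    Returns (frame, peptide) pairs with frame in (+1, +2, +3, -1, -2, -3);
    minus frames read the reverse complement.  Codons containing N become
    X; stops are rendered '*'.  Trailing bases short of a codon are
    ignored.
    """
    seq = seq.upper()
    out = []
    rc = revcomp(seq)
    for frame in (1, 2, 3):
        for strand_seq, signed in ((seq, frame), (rc, -frame)):
            sub = strand_seq[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append((signed, str(Seq(sub).translate())))
    out.sort(key=lambda fp: (fp[0] < 0, abs(fp[0])))
    return out


def _frame_to_genomic(frame: int, pep_start: int, pep_end: int, seq_len: int) -> tuple[int, int]:
    """Map a peptide slice [pep_start, pep_end) in a frame to 1-based
    inclusive genomic coordinates (start > end on the minus strand)."""
    f = abs(frame) - 1
    nt_lo = f + 3 * pep_start          # 0-based first base in frame strand
    nt_hi = f + 3 * pep_end - 1        # 0-based last base
    if frame > 0:
        return nt_lo + 1, nt_hi + 1
    return seq_len - nt_lo, seq_len - nt_hi


def _alignment_stats(alignment, matrix) -> tuple[int, int, int]:
    """(identical columns, positive-scoring columns, total columns)."""
    target, query = alignment[0], alignment[1]  # gapped strings
    ident = positive = 0
    for a, b in zip(target, query):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
        try:
            if matrix[a, b] > 0:
                positive += 1
        except KeyError:
            pass
    return ident, positive, alignment.shape[1]


def translated_search(
    protein: str,
    genome: Sequence[SequenceRecord],
    config: TranslatedSearchConfig | None = None,
    query_id: str = "query",
) -> list[HitRecord]:
    """Local alignment of a protein against all six frames of every
    genome sequence; the best local alignment per frame is reported when
    its E-value passes the cutoff.

    Hits are sorted by bit score (descending), then E-value (ascending),
    then lowest target coordinate.
    """
    protein = protein.upper().rstrip("*")
    if len(protein) < 10:
        raise ValueError("protein query must be at least 10 residues")
    bad = set(protein) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"protein contains illegal residues {sorted(bad)}")
    config = config or TranslatedSearchConfig()
    aligner = config.aligner()
    matrix = aligner.substitution_matrix
    db_len = sum(len(rec) for rec in genome)
    mn = config.search_space if config.search_space else len(protein) * db_len
    lam, kk = config.karlin_lambda, config.karlin_k

    hits: list[HitRecord] = []
    for rec in genome:
        for frame, peptide in six_frame_translate(rec.seq):
            if len(peptide) == 0:
                continue
            score = aligner.score(peptide, protein)
            if score <= 0:
                continue
            e_value = kk * mn * math.exp(-lam * score)
            if e_value > config.evalue_cutoff:
                continue
            alignment = aligner.align(peptide, protein)[0]
            ident, positive, cols = _alignment_stats(alignment, matrix)
            t_segs, q_segs = alignment.aligned
            pep_start, pep_end = int(t_segs[0][0]), int(t_segs[-1][1])
            q_start, q_end = int(q_segs[0][0]) + 1, int(q_segs[-1][1])
            t_start, t_end = _frame_to_genomic(frame, pep_start, pep_end, len(rec))
            bit_score = (lam * score - math.log(kk)) / math.log(2)
            hits.append(
                HitRecord(
                    query_id=query_id,
                    target_seq=rec.id,
                    q_start=q_start,
                    q_end=q_end,
                    t_start=t_start,
                    t_end=t_end,
                    pct_identity=100 * ident / cols,
                    pct_similarity=100 * positive / cols,
                    aln_len=cols,
                    bit_score=round(bit_score, 1),
                    e_value=e_value,
                    frame=frame,
                )
            )
    hits.sort(key=lambda h: (-h.bit_score, h.e_value, h.t_low))
    return hits


def best_hit(hits: Iterable[HitRecord]) -> HitRecord | None:
    """Highest bit score, ties by lowest E-value, then lowest target
    coordinate -- the anchor-selection rule."""
    return min(
        hits, key=lambda h: (-h.bit_score, h.e_value, h.t_low), default=None
    )


def classify_conservation(
    proteins: Mapping[str, str],
    target_genome: Sequence[SequenceRecord] | None = None,
    threshold_pct: float = 50.0,
    criterion: str = "identity",
    config: TranslatedSearchConfig | None = None,
    hits: Mapping[str, Sequence[HitRecord]] | None = None,
) -> list[ConservationCall]:
    """Three-way conservation classification of genes against another assembly.

    ``proteins`` maps gene id to its translated product.  Hits are either
    computed internally against ``target_genome`` or supplied per gene
    (e.g. parsed from an external blast-tab file); supplied hits are
    still filtered at the configured E-value cutoff.
    """
    if criterion not in ("identity", "similarity"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if (target_genome is None) == (hits is None):
        raise ValueError("provide exactly one of target_genome or hits")
    config = config or TranslatedSearchConfig()
    calls = []
    for gene_id, protein in proteins.items():
        if not protein:
            raise ValueError(f"gene {gene_id!r} has no protein sequence")
        if hits is not None:
            gene_hits = [
                h for h in hits.get(gene_id, []) if h.e_value <= config.evalue_cutoff
            ]
        else:
            gene_hits = translated_search(protein, target_genome, config, query_id=gene_id)
        top = best_hit(gene_hits)
        if top is None:
            calls.append(ConservationCall(gene_id, "unique", None, None))
            continue
        value = top.pct_identity if criterion == "identity" else top.pct_similarity
        cls = "low_similarity" if value < threshold_pct else "common"
        calls.append(ConservationCall(gene_id, cls, top, value))
    return calls


def summarize_conservation(calls: Sequence[ConservationCall]) -> ConservationSummary:
    """Counts and 2-decimal percentages per conservation class
    (half-away-from-zero rounding)."""
    if not calls:
        raise ValueError("no calls to summarize")
    counts = {"common": 0, "low_similarity": 0, "unique": 0}
    for call in calls:
        counts[call.conservation_class] += 1
    total = len(calls)
    percentages = {cls: percent(n, total, 2) for cls, n in counts.items()}
    return ConservationSummary(counts, percentages, total)
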