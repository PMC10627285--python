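"""Gene-anchor synteny between two assemblies: correspondence, chimeras,
inversion blocks.

In repeat-dense genomes whole-sequence alignment is dominated by
dispersed elements, so synteny is anchored on genes instead: each gene
from nonrepetitive regions of assembly A is assigned at most one anchor
in assembly B -- its best translated-search hit (highest bit score,
lowest E-value, lowest target coordinate).  Per-chromosome anchor counts
summarize correspondence and flag chimeric chromosomes (anchors split
substantially between two targets); runs of anchors monotonic in the
target coordinate are chained into forward/inverted blocks, and inverted
blocks of sufficient size are reported as inversions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .conservation import TranslatedSearchConfig, best_hit, translated_search
from .core import GenomicInterval, HitRecord, SequenceRecord
from .intervals import interval_overlap, overlap_length

__all__ = [
    "Anchor",
    "CorrespondenceRow",
    "SyntenyBlock",
    "nonrepetitive_genes",
    "build_anchors",
    "anchors_from_hits",
    "correspondence_table",
    "inversion_blocks",
]


@dataclass
class Anchor:
    gene_id: str
    query: GenomicInterval
    target: GenomicInterval
    orientation: str  # + | -
    bit_score: float
    e_value: float

    @property
    def query_mid(self) -> float:
        return (self.query.start + self.query.end) / 2

    @property
    def target_mid(self) -> float:
        return (self.target.start + self.target.end) / 2


@dataclass
class CorrespondenceRow:
    query_chromosome: str
    target_chromosome: str
    anchor_count: int
    fraction: float


@dataclass
class SyntenyBlock:
    query_chromosome: str
    target_chromosome: str
    anchors: list  # member Anchor objects in query order
    orientation: str  # forward | inverted

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def query_span(self) -> tuple[int, int]:
        return self.anchors[0].query.start, self.anchors[-1].query.end

    @property
    def gene_ids(self) -> list[str]:
        return [a.gene_id for a in self.anchors]


def nonrepetitive_genes(
    genes: Sequence[GenomicInterval],
    repeat_mask: Sequence[GenomicInterval],
    mode: str = "zero_overlap",
    max_overlap_fraction: float = 0.0,
) -> list[GenomicInterval]:
    """Genes lying in nonrepetitive sequence.

    ``zero_overlap`` (default) keeps genes with no repeat overlap at all;
    ``max_overlap`` keeps genes whose repeat-covered fraction is at most
    ``max_overlap_fraction``.
    """
    if mode == "zero_overlap":
        return interval_overlap(genes, repeat_mask, mode="nonoverlapping_a")
    if mode == "max_overlap":
        out = []
        for g in genes:
            covered = overlap_length(g, repeat_mask)
            if covered / len(g) <= max_overlap_fraction:
                out.append(g)
        return out
    raise ValueError(f"unknown mode {mode!r}")


def _hit_to_anchor(gene: GenomicInterval, hit: HitRecord) -> Anchor:
    lo, hi = sorted((hit.t_start, hit.t_end))
    target = GenomicInterval(hit.target_seq, lo - 1, hi, hit.strand, gene.name)
    # anchor orientation relative to the gene's own strand: a minus-strand
    # gene hitting the minus strand of B is collinear (+)
    flipped = gene.strand == "-"
    orientation = hit.strand if not flipped else ("-" if hit.strand == "+" else "+")
    return Anchor(
        gene_id=gene.name,
        query=gene,
        target=target,
        orientation=orientation,
        bit_score=hit.bit_score,
        e_value=hit.e_value,
    )


def build_anchors(
    proteins: Mapping[str, str],
    gene_intervals: Sequence[GenomicInterval],
    target_assembly: Sequence[SequenceRecord],
    config: TranslatedSearchConfig | None = None,
) -> list[Anchor]:
    """One anchor per gene at most: its best translated hit in the target.

    Because only the single best hit is kept, spurious multi-locus hits
    caused by dispersed repeats do not produce anchors.  Genes without a
    qualifying hit (E-value above cutoff) have no anchor.  Anchors are
    returned sorted by query position.
    """
    config = config or TranslatedSearchConfig()
    by_id = {g.name: g for g in gene_intervals}
    anchors = []
    for gene_id, protein in proteins.items():
        gene = by_id.get(gene_id)
        if gene is None:
            raise ValueError(f"protein {gene_id!r} has no gene interval")
        hits = translated_search(protein, target_assembly, config, query_id=gene_id)
        top = best_hit(hits)
        if top is not None:
            anchors.append(_hit_to_anchor(gene, top))
    anchors.sort(key=lambda a: (a.query.seq_id, a.query.start))
    return anchors


def anchors_from_hits(
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    gene_intervals: Sequence[GenomicInterval],
    evalue_cutoff: float = 1.0e-10,
) -> list[Anchor]:
    """Build anchors from precomputed hit tables (blast-tab input path)."""
    by_id = {g.name: g for g in gene_intervals}
    anchors = []
    for gene_id, hits in hits_by_gene.items():
        gene = by_id.get(gene_id)
        if gene is None:
            raise ValueError(f"hits for unknown gene {gene_id!r}")
        top = best_hit([h for h in hits if h.e_value <= evalue_cutoff])
        if top is not None:
            anchors.append(_hit_to_anchor(gene, top))
    anchors.sort(key=lambda a: (a.query.seq_id, a.query.start))
    return anchors


def correspondence_table(
    anchors: Sequence[Anchor],
    majority_fraction: float = 0.8,
    chimera_fraction: float = 0.25,
) -> tuple[list[CorrespondenceRow], dict[str, str]]:
    """Anchor counts per (query, target) chromosome pair, plus labels.

    A query chromosome is ``one_to_one`` when its top target holds at
    least ``majority_fraction`` of its anchors; ``chimeric`` when the top
    two targets each hold at least ``chimera_fraction`` and jointly at
    least ``majority_fraction``; otherwise ``dispersed``.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for a in anchors:
        counts[a.query.seq_id][a.target.seq_id] += 1
    rows: list[CorrespondenceRow] = []
    labels: dict[str, str] = {}
    for qchr in sorted(counts):
        per_target = counts[qchr]
        total = sum(per_target.values())
        ranked = sorted(per_target.items(), key=lambda kv: (-kv[1], kv[0]))
        for tchr, n in ranked:
            rows.append(CorrespondenceRow(qchr, tchr, n, n / total))
        top_frac = ranked[0][1] / total
        if top_frac >= majority_fraction:
            labels[qchr] = "one_to_one"
        elif (
            len(ranked) >= 2
            and ranked[0][1] / total >= chimera_fraction
            and ranked[1][1] / total >= chimera_fraction
            and (ranked[0][1] + ranked[1][1]) / total >= majority_fraction
        ):
            labels[qchr] = "chimeric"
        else:
            labels[qchr] = "dispersed"
    return rows, labels


def correspondence_frame(rows: Sequence[CorrespondenceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.query_chromosome, r.target_chromosome, r.anchor_count, r.fraction)
            for r in rows
        ],
        columns=["query_chromosome", "target_chromosome", "anchor_count", "fraction"],
    )


def _chain(anchors: list[Anchor], max_gap_anchors: int) -> list[list[Anchor]]:
    """Greedy chaining of query-ordered anchors (one target chromosome)
    into maximal target-monotone runs, tolerating up to
    ``max_gap_anchors`` consecutive outliers before the block is closed.
    Accumulated outliers seed the next block, so an inversion boundary
    is resolved to within one anchor."""
    blocks: list[list[Anchor]] = []
    cur: list[Anchor] = []
    direction = 0  # 0 unknown, +1 increasing target, -1 decreasing
    pending: list[Anchor] = []

    def _fits(a: Anchor) -> bool:
        nonlocal direction
        if not cur:
            return True
        delta = a.target_mid - cur[-1].target_mid
        if direction == 0:
            direction = 1 if delta >= 0 else -1
            return True
        return (delta >= 0) == (direction > 0)

    def _close():
        nonlocal cur, direction
        if cur:
            blocks.append(cur)
        cur = []
        direction = 0

    i = 0
    while i < len(anchors):
        a = anchors[i]
        if _fits(a):
            cur.append(a)
            pending = []
        else:
            pending.append(a)
            if len(pending) > max_gap_anchors:
                _close()
                # restart from the held-back outliers
                for b in pending:
                    if _fits(b):
                        cur.append(b)
                    else:
                        _close()
                        cur.append(b)
                pending = []
        i += 1
    if pending:
        _close()
        for b in pending:
            if _fits(b):
                cur.append(b)
            else:
                _close()
                cur.append(b)
    _close()
    return blocks


def inversion_blocks(
    anchors: Sequence[Anchor],
    min_block_anchors: int = 5,
    max_gap_anchors: int = 2,
) -> list[SyntenyBlock]:
    """Chain anchors into forward/inverted synteny blocks.

    Anchors are processed per query chromosome in query order; a new
    block starts whenever the target chromosome changes or target
    monotonicity breaks (beyond the outlier tolerance).  Block
    orientation is the direction of target coordinates along the block;
    a single-anchor block takes its anchor's orientation.  All blocks
    are returned; callers filter for ``inverted`` blocks with
    ``n_anchors >= min_block_anchors`` to report inversions (see
    ``called_inversions``).
    """
    by_q: dict[str, list[Anchor]] = defaultdict(list)
    for a in anchors:
        by_q[a.query.seq_id].append(a)
    blocks: list[SyntenyBlock] = []
    for qchr in sorted(by_q):
        ordered = sorted(by_q[qchr], key=lambda a: a.query.start)
        # split by target chromosome runs first
        runs: list[list[Anchor]] = []
        for a in ordered:
            if runs and runs[-1][-1].target.seq_id == a.target.seq_id:
                runs[-1].append(a)
            else:
                runs.append([a])
        for run in runs:
            for chain in _chain(run, max_gap_anchors):
                if len(chain) >= 2:
                    orientation = (
                        "forward"
                        if chain[-1].target_mid >= chain[0].target_mid
                        else "inverted"
                    )
                else:
                    orientation = "inverted" if chain[0].orientation == "-" else "forward"
                blocks.append(
                    SyntenyBlock(qchr, run[0].target.seq_id, chain, orientation)
                )
    return blocks


def called_inversions(
    blocks: Sequence[SyntenyBlock], min_block_anchors: int = 5
) -> list[SyntenyBlock]:
    """Inverted blocks large enough to call as inversions."""
    return [
        b for b in blocks if b.orientation == "inverted" and b.n_anchors >= min_block_anchors
    ]
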