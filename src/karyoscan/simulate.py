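"""Synthetic genomes, rearranged relatives, and clade-structured read panels.

Every downstream detector in the package is exercised against genomes
built here with planted truth: chromosomes carry terminal telomere
arrays per an explicit plan, dispersed repeat families of stated classes
and target genome fractions, and interspersed protein-coding genes in the
repeat-free space.  A rearrangement engine derives a relative genome by
inversions, translocations, fissions and fusions while lifting the gene
annotation through every edit, and a clade-panel simulator emits
uniform-coverage read placements whose mapped/unmapped pattern encodes a
planted clade structure of shared and private gene content.

All randomness flows from the single integer seed of each spec, so every
artifact is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core import GenomicInterval, SequenceRecord, revcomp
from .coverage import Placement

__all__ = [
    "RepeatFamilySpec",
    "GenomeSpec",
    "CladePanelSpec",
    "TruthTables",
    "RearrangementOp",
    "PanelResult",
    "simulate_genome",
    "derive_rearranged",
    "simulate_clade_panel",
    "linearize_circular",
    "random_sequence",
    "random_coding_sequence",
    "translate_genes",
]

REPEAT_CLASSES = ("LINE", "LTR", "DNA", "RC", "Unclassified", "Simple")
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class RepeatFamilySpec:
    name: str
    repeat_class: str
    consensus_length: int
    target_fraction: float
    divergence: float = 0.05

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")
        if not 0 <= self.target_fraction <= 1:
            raise ValueError("target_fraction must be in [0, 1]")
        if not 0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        if self.consensus_length < 10:
            raise ValueError("consensus_length must be >= 10")


@dataclass
class GenomeSpec:
    chromosome_lengths: Sequence[int] = (200_000, 150_000)
    telomere_unit: str = "CCCTAA"
    telomere_copies: int = 10
    telomere_plan: Sequence[str] | None = None  # both|five_prime|three_prime|none
    gc_target: float = 0.44
    repeat_families: Sequence[RepeatFamilySpec] = ()
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 1500)
    seed: int = 0

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.telomere_plan is None:
            self.telomere_plan = ["both"] * self.n_chromosomes
        if len(self.telomere_plan) != self.n_chromosomes:
            raise ValueError("telomere_plan length must match chromosome count")
        for plan in self.telomere_plan:
            if plan not in ("both", "five_prime", "three_prime", "none"):
                raise ValueError(f"unknown telomere plan {plan!r}")


@dataclass
class CladePanelSpec:
    clades: Sequence[tuple[str, Sequence[str]]] = (
        ("clade1", ("t1a", "t1b", "t1c")),
        ("clade2", ("t2a", "t2b", "t2c")),
        ("clade3", ("t3a", "t3b", "t3c")),
    )
    n_core_genes: int = 60
    n_clade_genes: int = 25
    n_private_genes: int = 15
    gene_length: int = 300
    spacer_length: int = 100
    read_length: int = 100
    coverage_depth: float = 10.0
    reference_taxa: Sequence[str] | None = None  # defaults: first taxon of clades 1 and 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_depth <= 0:
            raise ValueError("coverage_depth must be positive")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        taxa = [t for _, members in self.clades for t in members]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names across clades")
        if self.reference_taxa is None:
            self.reference_taxa = [self.clades[0][1][0], self.clades[1][1][0]]
        for ref in self.reference_taxa:
            if ref not in taxa:
                raise ValueError(f"reference taxon {ref!r} not in any clade")

    @property
    def taxa(self) -> list[str]:
        return [t for _, members in self.clades for t in members]


@dataclass
class TruthTables:
    telomeres: dict  # (seq_id, end) -> GenomicInterval
    repeats: list  # GenomicInterval with family/class attrs
    genes: list  # GenomicInterval, name = gene id
    gene_sequences: dict  # gene id -> oriented coding DNA
    rearrangements: list = field(default_factory=list)
    dropped_genes: list = field(default_factory=list)


@dataclass
class RearrangementOp:
    kind: str  # inversion | translocation | fusion | fission
    seq_id: str
    start: int | None = None
    end: int | None = None
    partner: str | None = None
    position: int | None = None
    new_name: str | None = None


@dataclass
class PanelResult:
    presence: pd.DataFrame  # taxa x gene ids (bool)
    references: dict  # ref name -> (SequenceRecord, list[GenomicInterval])
    placements: dict  # (taxon, ref name) -> list[Placement]
    gene_lengths: dict  # gene id -> bp


# ---------------------------------------------------------------------------
# sequence building blocks

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """GC-biased i.i.d. DNA."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(4, size=length, p=p)
    return _BASES[draw].tobytes().decode()


def random_coding_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """GC-biased open reading frame: ``length`` is rounded down to a codon
    multiple; internal stop codons are resampled."""
    length -= length % 3
    codons = []
    for _ in range(length // 3):
        codon = random_sequence(rng, 3, gc)
        while codon in _STOP_CODONS:
            codon = random_sequence(rng, 3, gc)
        codons.append(codon)
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute with a uniformly different base
        subs = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
        same = subs == arr[hit]
        while same.any():
            subs[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
            same = subs == arr[hit]
        arr[hit] = subs
    return arr.tobytes().decode()


def translate_genes(truth: TruthTables) -> dict[str, str]:
    """Protein products of the planted genes (oriented coding sequences)."""
    return {
        gid: str(Seq(seq).translate()) for gid, seq in truth.gene_sequences.items()
    }


# ---------------------------------------------------------------------------
# genome simulation


def _place_nonoverlapping(
    rng: np.random.Generator,
    occupied: np.ndarray,
    length: int,
    max_tries: int = 200,
) -> int | None:
    """Rejection-sample a start so [start, start+length) is entirely free."""
    n = len(occupied)
    if length > n:
        return None
    cum = np.concatenate([[0], np.cumsum(occupied.astype(np.int64))])
    for _ in range(max_tries):
        start = int(rng.integers(0, n - length + 1))
        if cum[start + length] - cum[start] == 0:
            return start
    return None


def simulate_genome(spec: GenomeSpec) -> tuple[list[SequenceRecord], TruthTables]:
    """Build an assembly with planted telomeres, repeats and genes.

    Deterministic given the spec seed.  Repeat copies are placed
    non-overlapping by rejection sampling and the realized masked
    fraction lands within about +-10% (relative) of each family's
    target; realized GC tracks ``gc_target`` within +-0.02 because both
    the background and the repeat consensus sequences are drawn from the
    same GC-biased base distribution.
    """
    rng = np.random.default_rng(spec.seed)
    total_len = int(sum(spec.chromosome_lengths))
    unit = spec.telomere_unit.upper()
    telo_len = len(unit) * spec.telomere_copies

    # feasibility: telomeres + repeats + genes must fit
    repeat_total = sum(f.target_fraction for f in spec.repeat_families) * total_len
    gene_total = spec.n_genes * sum(spec.gene_length_range) / 2
    telo_total = sum(
        telo_len * (2 if p == "both" else 0 if p == "none" else 1)
        for p in spec.telomere_plan
    )
    if repeat_total + gene_total + telo_total > 0.95 * total_len:
        raise ValueError(
            "infeasible spec: telomeres + repeats + genes exceed genome capacity"
        )

    consensi = {
        fam.name: random_sequence(rng, fam.consensus_length, spec.gc_target)
        for fam in spec.repeat_families
    }

    chrom_names = [f"chr{i + 1:02d}" for i in range(spec.n_chromosomes)]
    chroms: dict[str, np.ndarray] = {}
    occupied: dict[str, np.ndarray] = {}
    telomere_truth: dict = {}
    repeat_truth: list[GenomicInterval] = []

    for name, length, plan in zip(chrom_names, spec.chromosome_lengths, spec.telomere_plan):
        seq = np.frombuffer(
            random_sequence(rng, length, spec.gc_target).encode(), dtype=np.uint8
        ).copy()
        occ = np.zeros(length, dtype=bool)
        if plan in ("both", "five_prime"):
            arr = (unit * spec.telomere_copies).encode()
            seq[:telo_len] = np.frombuffer(arr, dtype=np.uint8)
            occ[:telo_len] = True
            telomere_truth[(name, "five_prime")] = GenomicInterval(
                name, 0, telo_len, "+", f"{name}_5p", kind="telomere"
            )
        if plan in ("both", "three_prime"):
            arr = (revcomp(unit) * spec.telomere_copies).encode()
            seq[length - telo_len :] = np.frombuffer(arr, dtype=np.uint8)
            occ[length - telo_len :] = True
            telomere_truth[(name, "three_prime")] = GenomicInterval(
                name, length - telo_len, length, "-", f"{name}_3p", kind="telomere"
            )
        chroms[name] = seq
        occupied[name] = occ

    # dispersed repeat families, copies allocated per chromosome by length
    lengths = np.array(spec.chromosome_lengths, dtype=float)
    for fam in spec.repeat_families:
        target_bases = fam.target_fraction * total_len
        n_copies = int(round(target_bases / fam.consensus_length))
        per_chrom = rng.multinomial(n_copies, lengths / lengths.sum())
        copy_idx = 0
        for name, n_here in zip(chrom_names, per_chrom):
            for _ in range(n_here):
                start = _place_nonoverlapping(
                    rng, occupied[name], fam.consensus_length
                )
                if start is None:
                    continue
                copy_seq = _mutate(rng, consensi[fam.name], fam.divergence)
                strand = "+" if rng.random() < 0.5 else "-"
                ins = copy_seq if strand == "+" else revcomp(copy_seq)
                end = start + fam.consensus_length
                chroms[name][start:end] = np.frombuffer(ins.encode(), dtype=np.uint8)
                occupied[name][start:end] = True
                repeat_truth.append(
                    GenomicInterval(
                        name, start, end, strand,
                        name=f"{fam.name}_{copy_idx:05d}", kind="repeat",
                        attrs={"family": fam.name, "repeat_class": fam.repeat_class},
                    )
                )
                copy_idx += 1

    # genes in repeat- and telomere-free space
    gene_truth: list[GenomicInterval] = []
    gene_seqs: dict[str, str] = {}
    gene_chrom = rng.choice(len(chrom_names), size=spec.n_genes, p=lengths / lengths.sum())
    lo, hi = spec.gene_length_range
    for i in range(spec.n_genes):
        name = chrom_names[int(gene_chrom[i])]
        glen = int(rng.integers(lo, hi + 1))
        glen -= glen % 3
        start = _place_nonoverlapping(rng, occupied[name], glen)
        if start is None:
            raise ValueError(
                "infeasible spec: could not place all genes in repeat-free space"
            )
        coding = random_coding_sequence(rng, glen, spec.gc_target)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = coding if strand == "+" else revcomp(coding)
        chroms[name][start : start + glen] = np.frombuffer(
            inserted.encode(), dtype=np.uint8
        )
        occupied[name][start : start + glen] = True
        gid = f"g{i + 1:05d}"
        gene_truth.append(
            GenomicInterval(
                name, start, start + glen, strand, gid, kind="gene",
                attrs={"feature_type": "gene"},
            )
        )
        gene_seqs[gid] = coding

    assembly = [
        SequenceRecord(name, chroms[name].tobytes().decode()) for name in chrom_names
    ]
    gene_truth.sort(key=lambda g: (g.seq_id, g.start))
    repeat_truth.sort(key=lambda r: (r.seq_id, r.start))
    truth = TruthTables(
        telomeres=telomere_truth,
        repeats=repeat_truth,
        genes=gene_truth,
        gene_sequences=gene_seqs,
    )
    return assembly, truth


# ---------------------------------------------------------------------------
# rearrangements


def _lift_inversion(genes, seq_id, start, end, dropped):
    out = []
    for g in genes:
        if g.seq_id != seq_id or g.end <= start or g.start >= end:
            out.append(g)
        elif start <= g.start and g.end <= end:
            flipped = "-" if g.strand == "+" else "+" if g.strand == "-" else "."
            out.append(
                replace(g, start=start + end - g.end, end=start + end - g.start,
                        strand=flipped)
            )
        else:
            dropped.append((g.name, "spans inversion breakpoint"))
    return out


def derive_rearranged(
    assembly: Sequence[SequenceRecord],
    genes: Sequence[GenomicInterval],
    ops: Sequence[RearrangementOp],
) -> tuple[list[SequenceRecord], list[dict], list[GenomicInterval], list]:
    """Apply structural rearrangements and lift the gene annotation.

    Ops are applied in order; coordinates refer to the assembly state at
    the time each op is applied.  Inversions listed on the same sequence
    must not overlap.  Genes spanning any breakpoint are dropped and
    logged.  Returns (assembly, log, lifted genes, dropped genes).
    """
    inversions: dict[str, list[tuple[int, int]]] = {}
    for op in ops:
        if op.kind == "inversion":
            for s, e in inversions.get(op.seq_id, []):
                if op.start < e and s < op.end:
                    raise ValueError(
                        f"overlapping inversions on {op.seq_id} in one pass"
                    )
            inversions.setdefault(op.seq_id, []).append((op.start, op.end))

    seqs = {rec.id: rec.seq for rec in assembly}
    order = [rec.id for rec in assembly]
    genes = list(genes)
    dropped: list = []
    log: list[dict] = []

    for op in ops:
        if op.seq_id not in seqs:
            raise ValueError(f"rearrangement references unknown sequence {op.seq_id!r}")
        seq = seqs[op.seq_id]
        if op.kind == "inversion":
            s, e = op.start, op.end
            if not 0 <= s < e <= len(seq):
                raise ValueError(f"inversion {s}-{e} out of range on {op.seq_id}")
            seqs[op.seq_id] = seq[:s] + revcomp(seq[s:e]) + seq[e:]
            genes = _lift_inversion(genes, op.seq_id, s, e, dropped)
            log.append({"op": "inversion", "seq_id": op.seq_id, "start": s, "end": e})
        elif op.kind == "fission":
            pos = op.position
            if not 0 < pos < len(seq):
                raise ValueError(f"fission position {pos} out of range on {op.seq_id}")
            left, right = f"{op.seq_id}.1", f"{op.seq_id}.2"
            seqs[left], seqs[right] = seq[:pos], seq[pos:]
            del seqs[op.seq_id]
            idx = order.index(op.seq_id)
            order[idx : idx + 1] = [left, right]
            new_genes = []
            for g in genes:
                if g.seq_id != op.seq_id:
                    new_genes.append(g)
                elif g.end <= pos:
                    new_genes.append(replace(g, seq_id=left))
                elif g.start >= pos:
                    new_genes.append(replace(g, seq_id=right, start=g.start - pos, end=g.end - pos))
                else:
                    dropped.append((g.name, "spans fission breakpoint"))
            genes = new_genes
            log.append({"op": "fission", "seq_id": op.seq_id, "position": pos,
                        "products": [left, right]})
        elif op.kind == "fusion":
            if op.partner not in seqs:
                raise ValueError(f"fusion partner {op.partner!r} unknown")
            new_name = op.new_name or f"{op.seq_id}+{op.partner}"
            offset = len(seqs[op.seq_id])
            seqs[new_name] = seqs[op.seq_id] + seqs[op.partner]
            genes = [
                replace(g, seq_id=new_name) if g.seq_id == op.seq_id
                else replace(g, seq_id=new_name, start=g.start + offset, end=g.end + offset)
                if g.seq_id == op.partner
                else g
                for g in genes
            ]
            idx = order.index(op.seq_id)
            order[idx] = new_name
            order.remove(op.partner)
            del seqs[op.seq_id], seqs[op.partner]
            log.append({"op": "fusion", "seq_id": op.seq_id, "partner": op.partner,
                        "product": new_name, "junction": offset})
        elif op.kind == "translocation":
            s, e, pos = op.start, op.end, op.position
            if op.partner not in seqs:
                raise ValueError(f"translocation partner {op.partner!r} unknown")
            if not 0 <= s < e <= len(seq):
                raise ValueError(f"translocation segment {s}-{e} out of range")
            segment = seq[s:e]
            seqs[op.seq_id] = seq[:s] + seq[e:]
            dest = seqs[op.partner]
            if not 0 <= pos <= len(dest):
                raise ValueError(f"translocation insertion point {pos} out of range")
            seqs[op.partner] = dest[:pos] + segment + dest[pos:]
            seg_len = e - s
            new_genes = []
            for g in genes:
                if g.seq_id == op.seq_id:
                    if g.end <= s:
                        new_genes.append(g)
                    elif g.start >= e:
                        new_genes.append(replace(g, start=g.start - seg_len, end=g.end - seg_len))
                    elif s <= g.start and g.end <= e:
                        new_genes.append(
                            replace(g, seq_id=op.partner,
                                    start=pos + g.start - s, end=pos + g.end - s)
                        )
                    else:
                        dropped.append((g.name, "spans translocation breakpoint"))
                elif g.seq_id == op.partner:
                    if g.end <= pos:
                        new_genes.append(g)
                    elif g.start >= pos:
                        new_genes.append(replace(g, start=g.start + seg_len, end=g.end + seg_len))
                    else:
                        dropped.append((g.name, "spans translocation insertion point"))
                else:
                    new_genes.append(g)
            genes = new_genes
            log.append({"op": "translocation", "seq_id": op.seq_id, "start": s,
                        "end": e, "partner": op.partner, "position": pos})
        else:
            raise ValueError(f"unknown rearrangement kind {op.kind!r}")

    out_assembly = [SequenceRecord(name, seqs[name]) for name in order]
    genes = sorted(genes, key=lambda g: (g.seq_id, g.start))
    return out_assembly, log, genes, dropped


# ---------------------------------------------------------------------------
# clade panels


def simulate_clade_panel(spec: CladePanelSpec) -> PanelResult:
    """Simulate a panel of taxa with clade-structured gene content and
    uniform-coverage read placements against one reference per designated
    reference taxon.

    Every taxon's gene set is core U its clade's genes U its private
    genes.  A reference is the genome of one taxon: its genes laid out
    with plain spacers, annotated by gene id.  For each (taxon,
    reference) pair, reads are drawn uniformly from the taxon's genes at
    ``coverage_depth``; a read from a gene present in the reference is
    emitted as a placement at that gene's reference location, and a read
    from a gene the reference lacks is emitted unmapped -- so the
    mapped-read fraction equals the shared gene fraction up to sampling
    noise, and the per-gene coverage pattern encodes the clades.
    """
    rng = np.random.default_rng(spec.seed)

    gene_sets: dict[str, list[str]] = {}
    core = [f"core{i:04d}" for i in range(spec.n_core_genes)]
    all_genes: list[str] = list(core)
    clade_genes: dict[str, list[str]] = {}
    for clade_id, members in spec.clades:
        cg = [f"{clade_id}_g{i:04d}" for i in range(spec.n_clade_genes)]
        clade_genes[clade_id] = cg
        all_genes.extend(cg)
        for taxon in members:
            pg = [f"{taxon}_p{i:04d}" for i in range(spec.n_private_genes)]
            all_genes.extend(pg)
            gene_sets[taxon] = core + cg + pg

    gene_lengths = {g: spec.gene_length for g in all_genes}
    presence = pd.DataFrame(
        [[g in set(gene_sets[t]) for g in all_genes] for t in spec.taxa],
        index=spec.taxa, columns=all_genes, dtype=bool,
    )

    # reference genomes: the designated taxa's genes with spacers
    references: dict = {}
    for ref_taxon in spec.reference_taxa:
        genes = gene_sets[ref_taxon]
        parts = []
        intervals = []
        pos = 0
        ref_name = f"ref_{ref_taxon}"
        for g in genes:
            spacer = random_sequence(rng, spec.spacer_length, 0.5)
            parts.append(spacer)
            pos += spec.spacer_length
            gseq = random_sequence(rng, gene_lengths[g], 0.5)
            parts.append(gseq)
            intervals.append(
                GenomicInterval(ref_name, pos, pos + gene_lengths[g], "+", g,
                                kind="gene", attrs={"feature_type": "gene"})
            )
            pos += gene_lengths[g]
        parts.append(random_sequence(rng, spec.spacer_length, 0.5))
        references[ref_name] = (
            SequenceRecord(ref_name, "".join(parts)), intervals,
        )

    placements: dict = {}
    for taxon in spec.taxa:
        for ref_name, (ref_rec, intervals) in references.items():
            by_id = {iv.name: iv for iv in intervals}
            plist: list[Placement] = []
            ridx = 0
            for g in gene_sets[taxon]:
                glen = gene_lengths[g]
                rl = spec.read_length
                # a read overlapping the gene may start up to rl-1 bases
                # upstream; sizing by the start window keeps the mean
                # realized depth over the gene at coverage_depth
                n_reads = int(round(spec.coverage_depth * (glen + rl - 1) / rl))
                iv = by_id.get(g)
                if iv is None:
                    for _ in range(n_reads):
                        plist.append(
                            Placement(f"{taxon}_{ref_name}_r{ridx:07d}", "*", 0, 0,
                                      "+", mapped=False)
                        )
                        ridx += 1
                    continue
                starts = rng.integers(iv.start - rl + 1, iv.end, size=n_reads)
                for s in starts:
                    s = max(0, int(s))
                    e = min(s + rl, len(ref_rec))
                    plist.append(
                        Placement(f"{taxon}_{ref_name}_r{ridx:07d}", ref_name, s, e,
                                  "+", mapped=True)
                    )
                    ridx += 1
            placements[(taxon, ref_name)] = plist

    return PanelResult(presence, references, placements, gene_lengths)


# ---------------------------------------------------------------------------
# circular molecules


def linearize_circular(circle: SequenceRecord, overlap_len: int) -> SequenceRecord:
    """Linearize a circular molecule with an exact terminal duplication:
    the output is the circle followed by its first ``overlap_len`` bases,
    the signature an assembler leaves when it walks past the origin."""
    if not 0 < overlap_len < len(circle.seq):
        raise ValueError(
            f"overlap_len must be in (0, {len(circle.seq)}), got {overlap_len}"
        )
    return SequenceRecord(
        circle.id, circle.seq + circle.seq[:overlap_len], circle.description
    )
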