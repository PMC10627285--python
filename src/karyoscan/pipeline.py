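"""End-to-end driver: simulate -> detect -> cluster -> report.

``run_pipeline`` exercises every analysis stage against a freshly
simulated genome with planted truth and writes all intermediate TSV /
FASTA artifacts plus a JSON summary and run manifest.  Given the same
configuration and seed the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .circular import detect_terminal_overlap, verify_circularity
from .conservation import TranslatedSearchConfig
from .core import GenomicInterval, SequenceRecord
from .coverage import build_depth_matrix, combine_and_cluster, gene_coverage, mapping_rate
from .io import write_bed, write_fasta, write_gff3
from .simulate import (
    CladePanelSpec,
    GenomeSpec,
    RearrangementOp,
    RepeatFamilySpec,
    linearize_circular,
    random_sequence,
    simulate_clade_panel,
    simulate_genome,
    derive_rearranged,
    translate_genes,
)
from .synteny import (
    build_anchors,
    called_inversions,
    correspondence_table,
    inversion_blocks,
    nonrepetitive_genes,
)
from .telomeres import TelomereScanConfig, classify_chromosome_ends, scan_telomeres
from .windows import call_enriched_regions, gc_profile, profiles_to_rows, repeat_density

logger = logging.getLogger("karyoscan")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their standard defaults
    (telomere unit CCCTAA at >= 5 copies; 50-kb GC and LTR windows and
    5-kb LINE windows; depth >= 3 for gene coverage; translated-search
    E-value cutoff 1.0e-10; 50% identity threshold; 50% enrichment
    threshold)."""

    seed: int = 0
    out_dir: str = "karyoscan_out"
    # telomere scan
    telomere_unit: str = "CCCTAA"
    telomere_min_copies: float = 5.0
    telomere_max_mismatch_fraction: float = 0.1
    telomere_end_window: int = 1000
    # window profiles
    gc_window: int = 50_000
    ltr_window: int = 50_000
    line_window: int = 5_000
    enrichment_threshold: float = 0.5
    # circularization
    min_overlap: int = 1000
    min_identity: float = 1.0
    # conservation / synteny
    evalue_cutoff: float = 1.0e-10
    similarity_threshold: float = 50.0
    criterion: str = "identity"
    majority_fraction: float = 0.8
    chimera_fraction: float = 0.25
    min_block_anchors: int = 5
    max_gap_anchors: int = 2
    # coverage clustering
    min_depth: int = 3
    linkage: str = "complete"
    n_clades: int = 3
    # demo genome sizing (desk-scale)
    demo_chromosome_lengths: tuple = (120_000, 100_000, 80_000)
    demo_n_genes: int = 45
    demo_mt_length: int = 24_000
    demo_mt_overlap: int = 3_000

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        coerced = dict(data)
        if "demo_chromosome_lengths" in coerced:
            coerced["demo_chromosome_lengths"] = tuple(coerced["demo_chromosome_lengths"])
        return cls(**coerced)


def _write_tsv(path: Path, rows, header: Sequence[str]) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full demo pipeline; returns the summary dict (also written
    to ``summary.json`` in the output directory)."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    summary: dict = {"seed": config.seed}

    # -- stage 1: simulate a genome with planted structure ------------------
    logger.info("[simulate] building demo genome (seed=%d)", config.seed)
    spec = GenomeSpec(
        chromosome_lengths=config.demo_chromosome_lengths,
        telomere_plan=["both", "five_prime", "none"][: len(config.demo_chromosome_lengths)],
        repeat_families=(
            RepeatFamilySpec("ltrA", "LTR", 4000, 0.20, 0.05),
            RepeatFamilySpec("lineB", "LINE", 1500, 0.05, 0.08),
        ),
        n_genes=config.demo_n_genes,
        seed=config.seed,
    )
    assembly, truth = simulate_genome(spec)
    write_fasta(assembly, out / "genome.fa")
    write_gff3(truth.genes, out / "genes.gff3")
    write_bed(truth.repeats, out / "repeats.bed")

    # -- stage 2: telomere scan --------------------------------------------
    telo_cfg = TelomereScanConfig(
        unit=config.telomere_unit,
        min_copies=config.telomere_min_copies,
        max_mismatch_fraction=config.telomere_max_mismatch_fraction,
        end_window=config.telomere_end_window,
    )
    hits = scan_telomeres(assembly, telo_cfg)
    labels, counts = classify_chromosome_ends(hits, assembly)
    _write_tsv(
        out / "telomeres.tsv",
        [
            (h.seq_id, h.contig_end, h.span.start, h.span.end, h.strand, h.copies, h.mismatches)
            for h in hits
        ],
        ["seq_id", "contig_end", "start", "end", "strand", "copies", "mismatches"],
    )
    planted = {
        (seq_id, end) for (seq_id, end) in truth.telomeres
    }
    detected = {(h.seq_id, h.contig_end) for h in hits}
    summary["telomeres"] = {
        "labels": labels,
        "counts": dict(counts),
        "planted_recovered": sorted(planted) == sorted(planted & detected),
    }
    logger.info("[telomeres] %s", dict(counts))

    # -- stage 3: window profiles ------------------------------------------
    seq_lengths = {rec.id: len(rec) for rec in assembly}
    gc_rows = []
    for rec in assembly:
        gc_rows.extend(profiles_to_rows(gc_profile(rec, config.gc_window, config.gc_window)))
    _write_tsv(out / "gc_profile.tsv", gc_rows, ["seq_id", "start", "end", "metric", "value"])
    line_prof = repeat_density(truth.repeats, seq_lengths, config.line_window, "LINE")
    ltr_prof = repeat_density(truth.repeats, seq_lengths, config.ltr_window, "LTR")
    _write_tsv(
        out / "repeat_density.tsv",
        profiles_to_rows(line_prof) + profiles_to_rows(ltr_prof),
        ["seq_id", "start", "end", "metric", "value"],
    )
    enriched = call_enriched_regions(line_prof, config.enrichment_threshold, seq_lengths=seq_lengths)
    summary["enriched_regions"] = len(enriched)

    # -- stage 4: mitochondrial circularization ----------------------------
    import numpy as np

    mt_rng = np.random.default_rng(config.seed + 7)
    circle = SequenceRecord("mt_demo", random_sequence(mt_rng, config.demo_mt_length, 0.22))
    raw = linearize_circular(circle, config.demo_mt_overlap)
    result = detect_terminal_overlap(raw, config.min_overlap, config.min_identity)
    write_fasta([result.trimmed_seq], out / "mt_trimmed.fa")
    summary["circularization"] = {
        "input_length": result.input_length,
        "overlap_length": result.overlap_length,
        "trimmed_length": result.trimmed_length,
        "circular": verify_circularity(result.trimmed_seq, min_overlap=config.min_overlap),
    }
    logger.info("[circularize] overlap=%d trimmed=%d", result.overlap_length, result.trimmed_length)

    # -- stage 5: clade panel, coverage, clustering ------------------------
    panel_spec = CladePanelSpec(seed=config.seed + 13)
    panel = simulate_clade_panel(panel_spec)
    cov_by_ref: dict[str, pd.DataFrame] = {}
    rates = {}
    for ref_name, (ref_rec, gene_ivs) in panel.references.items():
        rows = {}
        for taxon in panel_spec.taxa:
            placements = panel.placements[(taxon, ref_name)]
            depth = build_depth_matrix(placements, {ref_rec.id: len(ref_rec)})
            rows[taxon] = gene_coverage(depth, gene_ivs, config.min_depth)
            rates[(taxon, ref_name)] = mapping_rate(placements)
        cov_by_ref[ref_name] = pd.DataFrame.from_dict(rows, orient="index")
    combined, clusters = combine_and_cluster(cov_by_ref, config.n_clades, config.linkage)
    combined.to_csv(out / "coverage_matrix.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(clusters.newick + "\n")
    _write_tsv(
        out / "clusters.tsv",
        sorted(clusters.labels.items()),
        ["sample", "cluster"],
    )
    planted_clades = {frozenset(members) for _, members in panel_spec.clades}
    recovered = set(clusters.clusters()) == planted_clades
    summary["clades"] = {
        "k": config.n_clades,
        "recovered_planted": recovered,
        "n_clusters": len(clusters.clusters()),
        "mapping_rates": {f"{t}|{r}": round(v, 4) for (t, r), v in sorted(rates.items())},
    }
    logger.info("[cluster] planted clades recovered: %s", recovered)

    # -- stage 6: synteny against a rearranged relative --------------------
    syn_spec = GenomeSpec(
        chromosome_lengths=(9000, 9000),
        telomere_plan=["none", "none"],
        n_genes=24,
        gene_length_range=(150, 300),
        seed=config.seed + 29,
    )
    anc_assembly, anc_truth = simulate_genome(syn_spec)
    mid0 = len(anc_assembly[0]) // 2
    ops = [
        RearrangementOp("inversion", "chr01", mid0 - 3000, mid0 + 3000),
    ]
    der_assembly, rlog, der_genes, der_dropped = derive_rearranged(
        anc_assembly, anc_truth.genes, ops
    )
    proteins = translate_genes(anc_truth)
    keep = nonrepetitive_genes(anc_truth.genes, anc_truth.repeats)
    keep_ids = {g.name for g in keep}
    search_cfg = TranslatedSearchConfig(evalue_cutoff=config.evalue_cutoff)
    anchors = build_anchors(
        {gid: p for gid, p in proteins.items() if gid in keep_ids},
        anc_truth.genes,
        der_assembly,
        search_cfg,
    )
    rows, chrom_labels = correspondence_table(
        anchors, config.majority_fraction, config.chimera_fraction
    )
    blocks = inversion_blocks(anchors, config.min_block_anchors, config.max_gap_anchors)
    inversions = called_inversions(blocks, config.min_block_anchors)
    _write_tsv(
        out / "anchors.tsv",
        [
            (a.gene_id, a.query.seq_id, a.query.start, a.query.end,
             a.target.seq_id, a.target.start, a.target.end, a.orientation,
             a.bit_score)
            for a in anchors
        ],
        ["gene", "qchr", "qstart", "qend", "tchr", "tstart", "tend", "orientation", "score"],
    )
    summary["synteny"] = {
        "n_anchors": len(anchors),
        "chromosome_labels": chrom_labels,
        "n_blocks": len(blocks),
        "n_inversions": len(inversions),
        "rearrangement_log": rlog,
    }
    logger.info("[synteny] %d anchors, %d inversion(s)", len(anchors), len(inversions))

    # -- report -------------------------------------------------------------
    summary["elapsed_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary


def validate_inputs(
    assembly: Sequence[SequenceRecord],
    intervals: Sequence[GenomicInterval] = (),
    proteins: Mapping[str, str] | None = None,
    placements=(),
) -> list[str]:
    """Cross-file consistency diagnostics: intervals within bounds,
    gene/protein id agreement, placement references known.  Returns a
    list of human-readable diagnostics; empty means consistent."""
    diags: list[str] = []
    lengths = {rec.id: len(rec) for rec in assembly}
    gene_ids = set()
    for iv in intervals:
        if iv.seq_id not in lengths:
            diags.append(f"interval {iv.name or iv.start}:{iv.end} references unknown sequence {iv.seq_id!r}")
        elif iv.end > lengths[iv.seq_id]:
            diags.append(
                f"interval {iv.name!r} ({iv.seq_id}:{iv.start}-{iv.end}) extends past "
                f"sequence end ({lengths[iv.seq_id]})"
            )
        if iv.kind == "gene" and iv.name:
            gene_ids.add(iv.name)
    if proteins is not None:
        for gid in sorted(gene_ids - set(proteins)):
            diags.append(f"gene {gid!r} has no protein translation")
        for gid in sorted(set(proteins) - gene_ids):
            diags.append(f"protein {gid!r} has no gene interval")
    for p in placements:
        if p.mapped and p.seq_id not in lengths:
            diags.append(f"placement {p.read_id!r} references unknown sequence {p.seq_id!r}")
    return diags
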