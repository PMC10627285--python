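"""Anchor building, chromosome correspondence, chimera and inversion calls."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import covered_positions, random_intervals
from karyoscan.conservation import TranslatedSearchConfig
from karyoscan.core import GenomicInterval, HitRecord, SequenceRecord
from karyoscan.simulate import (
    GenomeSpec,
    RearrangementOp,
    derive_rearranged,
    random_coding_sequence,
    random_sequence,
    simulate_genome,
    translate_genes,
)
from karyoscan.synteny import (
    Anchor,
    anchors_from_hits,
    build_anchors,
    called_inversions,
    correspondence_table,
    inversion_blocks,
    nonrepetitive_genes,
)


def make_anchor(gene_id, qchr, qpos, tchr, tpos, orientation="+", glen=100):
    return Anchor(
        gene_id=gene_id,
        query=GenomicInterval(qchr, qpos, qpos + glen, "+", gene_id),
        target=GenomicInterval(tchr, tpos, tpos + glen, orientation, gene_id),
        orientation=orientation,
        bit_score=100.0,
        e_value=1e-30,
    )


class TestNonrepetitiveGenes:
    def test_gene_inside_repeat_removed(self):
        genes = [GenomicInterval("s", 100, 200, "+", "g1", kind="gene")]
        mask = [GenomicInterval("s", 50, 300)]
        assert nonrepetitive_genes(genes, mask) == []

    def test_gene_clear_of_repeats_kept(self):
        genes = [GenomicInterval("s", 100, 200, "+", "g1", kind="gene")]
        mask = [GenomicInterval("s", 300, 400)]
        assert nonrepetitive_genes(genes, mask) == genes

    def test_matches_bruteforce(self, rng):
        genes = random_intervals(rng, 500, max_pos=5000, max_len=100)
        mask = random_intervals(rng, 200, max_pos=5000, max_len=300)
        mask_pos = covered_positions(mask)
        kept = nonrepetitive_genes(genes, mask)
        expect = [
            g
            for g in genes
            if not any((g.seq_id, p) in mask_pos for p in range(g.start, g.end))
        ]
        assert kept == expect

    def test_max_overlap_mode(self):
        genes = [GenomicInterval("s", 0, 100, "+", "g1", kind="gene")]
        mask = [GenomicInterval("s", 0, 30)]
        assert nonrepetitive_genes(genes, mask, "max_overlap", 0.5) == genes
        assert nonrepetitive_genes(genes, mask, "max_overlap", 0.2) == []


class TestBuildAnchors:
    def test_planted_one_to_one_copies(self, rng):
        """Genes copied verbatim into a second assembly anchor at their
        planted loci."""
        genes, proteins, parts = [], {}, []
        pos = 0
        for i in range(8):
            spacer = random_sequence(rng, 200, 0.5)
            orf = random_coding_sequence(rng, 300, 0.5)
            parts += [spacer, orf]
            pos += 200
            gid = f"g{i}"
            genes.append(GenomicInterval("qchr", pos, pos + 300, "+", gid, kind="gene"))
            proteins[gid] = str(Seq(orf).translate())
            pos += 300
        target = [SequenceRecord("tchr", "".join(parts))]
        anchors = build_anchors(proteins, genes, target)
        assert len(anchors) == 8
        for a, g in zip(anchors, genes):
            assert a.gene_id == g.name
            assert (a.target.start, a.target.end) == (g.start, g.end)
            assert a.orientation == "+"

    def test_duplicated_gene_anchor_is_higher_scoring_copy(self, rng):
        orf = random_coding_sequence(rng, 300, 0.5)
        protein = str(Seq(orf).translate())
        # mutate one copy at the DNA level
        mutated = list(orf)
        for p in range(0, 300, 7):
            mutated[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[p]]
        target_seq = (
            random_sequence(rng, 500, 0.5)
            + "".join(mutated)
            + random_sequence(rng, 500, 0.5)
            + orf
            + random_sequence(rng, 200, 0.5)
        )
        gene = GenomicInterval("q", 0, 300, "+", "g0", kind="gene")
        anchors = build_anchors({"g0": protein}, [gene], [SequenceRecord("t", target_seq)])
        assert len(anchors) == 1
        assert anchors[0].target.start == 1300  # the exact copy

    def test_equal_hits_tie_break_lower_coordinate(self):
        gene = GenomicInterval("q", 0, 300, "+", "g0", kind="gene")
        hits = {
            "g0": [
                HitRecord("g0", "t", 1, 100, 5001, 5300, 99.0, 99.0, 100, 200.0, 1e-50),
                HitRecord("g0", "t", 1, 100, 1001, 1300, 99.0, 99.0, 100, 200.0, 1e-50),
            ]
        }
        anchors = anchors_from_hits(hits, [gene])
        assert anchors[0].target.start == 1000


class TestCorrespondence:
    def test_all_anchors_one_target(self):
        anchors = [make_anchor(f"g{i}", "qA", i * 1000, "tB", i * 1000) for i in range(10)]
        rows, labels = correspondence_table(anchors)
        assert labels == {"qA": "one_to_one"}
        assert rows[0].fraction == 1.0

    def test_fractions_sum_to_one(self, rng):
        anchors = [
            make_anchor(f"g{i}", "qA", i * 500, f"t{int(rng.integers(4))}", i * 500)
            for i in range(40)
        ]
        rows, _ = correspondence_table(anchors)
        assert sum(r.fraction for r in rows) == pytest.approx(1.0)

    def test_even_spread_is_dispersed(self):
        anchors = [
            make_anchor(f"g{i}", "qA", i * 1000, f"t{i % 5}", i * 1000) for i in range(20)
        ]
        _, labels = correspondence_table(anchors)
        assert labels == {"qA": "dispersed"}

    def test_planted_fusion_called_chimeric(self):
        """A derived chromosome fused from halves of two ancestors is
        labeled chimeric with its two true sources."""
        spec = GenomeSpec(
            chromosome_lengths=(30_000, 30_000),
            telomere_plan=["none", "none"],
            n_genes=30,
            gene_length_range=(300, 600),
            seed=17,
        )
        asm, truth = simulate_genome(spec)
        ops = [
            RearrangementOp("fission", "chr01", position=15_000),
            RearrangementOp("fission", "chr02", position=15_000),
            RearrangementOp("fusion", "chr01.1", partner="chr02.2", new_name="der1"),
        ]
        _, _, lifted, dropped = derive_rearranged(asm, truth.genes, ops)
        # anchors from the derived genome's genes back to the ancestral one:
        # identity mapping via the lift table (search-free, the lift is truth)
        anchors = []
        ancestral = {g.name: g for g in truth.genes}
        for g in lifted:
            src = ancestral[g.name]
            anchors.append(
                Anchor(g.name, query=g, target=src, orientation="+",
                       bit_score=100.0, e_value=1e-40)
            )
        _, labels = correspondence_table(anchors)
        assert labels["der1"] == "chimeric"
        der_targets = {a.target.seq_id for a in anchors if a.query.seq_id == "der1"}
        assert der_targets == {"chr01", "chr02"}


class TestInversionBlocks:
    def test_collinear_anchors_single_forward_block(self):
        anchors = [make_anchor(f"g{i}", "q", i * 1000, "t", i * 1000) for i in range(12)]
        blocks = inversion_blocks(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward"
        assert called_inversions(blocks) == []

    def test_self_comparison_yields_no_inversions(self, rng):
        spec = GenomeSpec(
            chromosome_lengths=(20_000,), telomere_plan=["none"], n_genes=15,
            gene_length_range=(200, 400), seed=23,
        )
        _, truth = simulate_genome(spec)
        anchors = [
            Anchor(g.name, query=g, target=g, orientation="+", bit_score=99.0,
                   e_value=1e-40)
            for g in truth.genes
        ]
        blocks = inversion_blocks(anchors)
        assert all(b.orientation == "forward" for b in blocks)
        assert len(blocks) == 1

    def test_single_planted_inversion_breakpoints(self):
        """One planted inversion over 20 consecutive anchors gives exactly
        one inverted block, boundaries within one anchor of the plant."""
        n = 60
        inv_lo, inv_hi = 20, 40
        anchors = []
        for i in range(n):
            if inv_lo <= i < inv_hi:
                tpos = (inv_lo + inv_hi - 1 - i) * 1000
                ori = "-"
            else:
                tpos = i * 1000
                ori = "+"
            anchors.append(make_anchor(f"g{i:03d}", "q", i * 1000, "t", tpos, ori))
        blocks = inversion_blocks(anchors, min_block_anchors=5)
        inv = called_inversions(blocks, 5)
        assert len(inv) == 1
        ids = inv[0].gene_ids
        planted = [f"g{i:03d}" for i in range(inv_lo, inv_hi)]
        assert abs(len(ids) - len(planted)) <= 1
        assert ids[0] in planted[:2] and ids[-1] in planted[-2:]

    def test_two_planted_inversions_flanked_by_forward(self):
        anchors = []
        segments = [
            (0, 30, "+"), (30, 60, "-"), (60, 90, "+"), (90, 120, "-"), (120, 150, "+"),
        ]
        for lo, hi, ori in segments:
            for i in range(lo, hi):
                tpos = i if ori == "+" else (lo + hi - 1 - i)
                anchors.append(
                    make_anchor(f"g{i:03d}", "q", i * 500, "t", tpos * 500, ori, glen=80)
                )
        blocks = inversion_blocks(anchors, min_block_anchors=5)
        inv = called_inversions(blocks, 5)
        assert len(inv) == 2
        orientations = [b.orientation for b in blocks]
        assert orientations == ["forward", "inverted", "forward", "inverted", "forward"]

    def test_reversed_query_flips_orientations(self):
        anchors = [make_anchor(f"g{i}", "q", i * 1000, "t", i * 1000) for i in range(10)]
        qlen = 10_000
        flipped = [
            Anchor(
                a.gene_id,
                query=GenomicInterval("q", qlen - a.query.end, qlen - a.query.start,
                                      "-", a.gene_id),
                target=a.target,
                orientation="-",
                bit_score=a.bit_score,
                e_value=a.e_value,
            )
            for a in anchors
        ]
        fwd_blocks = inversion_blocks(anchors)
        rev_blocks = inversion_blocks(flipped)
        assert len(fwd_blocks) == len(rev_blocks) == 1
        assert fwd_blocks[0].orientation == "forward"
        assert rev_blocks[0].orientation == "inverted"

    def test_blocks_partition_query_disjointly(self, rng):
        anchors = []
        for i in range(50):
            tchr = "t1" if i < 25 else "t2"
            tpos = int(rng.integers(0, 50)) * 997
            anchors.append(make_anchor(f"g{i:03d}", "q", i * 1000, tchr, tpos))
        blocks = inversion_blocks(anchors, max_gap_anchors=1)
        seen = set()
        for b in blocks:
            for gid in b.gene_ids:
                assert gid not in seen
                seen.add(gid)


class TestEndToEndSearchAnchors:
    def test_planted_inversion_recovered_by_translated_search(self):
        """Simulate, invert a gene-dense interval between genes, rebuild
        anchors by translated search, and recover the inversion with
        breakpoints within one anchor."""
        spec = GenomeSpec(
            chromosome_lengths=(14_000,),
            telomere_plan=["none"],
            n_genes=18,
            gene_length_range=(150, 250),
            seed=31,
        )
        asm, truth = simulate_genome(spec)
        genes = sorted(truth.genes, key=lambda g: g.start)
        # breakpoints in intergenic space around genes 5..12
        lo = (genes[4].end + genes[5].start) // 2
        hi = (genes[12].end + genes[13].start) // 2
        inside = [g.name for g in genes[5:13]]
        derived, _, _, dropped = derive_rearranged(
            asm, truth.genes, [RearrangementOp("inversion", "chr01", lo, hi)]
        )
        assert dropped == []
        proteins = translate_genes(truth)
        anchors = build_anchors(proteins, truth.genes, derived)
        assert len(anchors) == 18
        inv = called_inversions(inversion_blocks(anchors, min_block_anchors=5), 5)
        assert len(inv) == 1
        ids = inv[0].gene_ids
        assert set(ids) <= set(inside) or set(inside) <= set(ids)
        assert abs(len(ids) - len(inside)) <= 1
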