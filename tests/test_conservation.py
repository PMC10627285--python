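"""Translated search and conservation classification.

The alignment engine is cross-checked against an independent quadratic
Smith-Waterman-Gotoh dynamic program written here, and the three-way
classification against panels with planted shared / diverged / private
genes.
"""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from karyoscan.conservation import (
    ConservationCall,
    TranslatedSearchConfig,
    classify_conservation,
    six_frame_translate,
    summarize_conservation,
    translated_search,
)
from karyoscan.core import SequenceRecord, revcomp
from karyoscan.simulate import random_coding_sequence, random_sequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")

# simple unambiguous back-translation table
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
AA = "".join(sorted(_CODON))


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


def sw_gotoh_score(a: str, b: str, open_cost: int = 12, extend_cost: int = 1) -> float:
    """Independent quadratic local affine-gap DP (first gap base costs
    ``open_cost``, each further base ``extend_cost``)."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(
                0.0,
                max(H[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s,
            )
            Ix[i, j] = max(H[i - 1, j] - open_cost, Ix[i - 1, j] - extend_cost,
                           Iy[i - 1, j] - open_cost)
            Iy[i, j] = max(H[i, j - 1] - open_cost, Iy[i, j - 1] - extend_cost,
                           Ix[i, j - 1] - open_cost)
            best = max(best, H[i, j])
    return best


class TestSixFrameTranslate:
    def test_codon_table(self):
        frames = dict(six_frame_translate("ATGAAATAA"))
        assert frames[1] == "MK*"

    def test_short_sequence_boundary(self):
        frames = dict(six_frame_translate("A"))
        assert all(p == "" for p in frames.values())
        assert set(frames) == {1, 2, 3, -1, -2, -3}

    def test_n_codons_become_x(self):
        assert dict(six_frame_translate("ATNAAA"))[1] == "XK"

    def test_reverse_complement_consistency(self, rng):
        """Minus-strand frames equal plus-strand frames of the reverse
        complement, for random sequences (independent double translation)."""
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(30, 120)), 0.5)
            fwd = dict(six_frame_translate(seq))
            rc = dict(six_frame_translate(revcomp(seq)))
            for f in (1, 2, 3):
                assert fwd[-f] == rc[f]


class TestTranslatedSearch:
    def test_planted_orf_is_top_hit(self, rng):
        """A protein translated from a planted 300-bp ORF hits back at 100%
        identity with the exact genomic span and frame."""
        orf = random_coding_sequence(rng, 300, 0.5)
        protein = str(Seq(orf).translate())
        left = random_sequence(rng, 1037, 0.5)
        genome = [SequenceRecord("g", left + orf + random_sequence(rng, 2000, 0.5))]
        hits = translated_search(protein, genome, query_id="q")
        top = hits[0]
        assert top.pct_identity == 100.0
        assert (top.t_start, top.t_end) == (1038, 1037 + 300)
        assert top.frame == (1037 % 3) + 1
        assert (top.q_start, top.q_end) == (1, 100)

    def test_planted_minus_strand_orf(self, rng):
        orf = random_coding_sequence(rng, 150, 0.5)
        protein = str(Seq(orf).translate())
        left = random_sequence(rng, 500, 0.5)
        genome = [SequenceRecord("g", left + revcomp(orf) + random_sequence(rng, 500, 0.5))]
        top = translated_search(protein, genome)[0]
        assert top.pct_identity == 100.0
        assert top.strand == "-"
        assert (min(top.t_start, top.t_end), max(top.t_start, top.t_end)) == (501, 650)

    def test_alignment_score_matches_dp_oracle_textbook_pair(self):
        """The classic HEAGAWGHEE / PAWHEAE pair: engine score equals the
        independent DP on the same matrix and gap costs."""
        protein = "HEAGAWGHEE"
        target_pep = "PAWHEAE"
        cfg = TranslatedSearchConfig()
        engine = cfg.aligner().score(target_pep, protein)
        assert engine == sw_gotoh_score(target_pep, protein)

    def test_alignment_scores_match_dp_oracle_random(self, rng):
        cfg = TranslatedSearchConfig()
        aligner = cfg.aligner()
        for _ in range(15):
            a = "".join(AA[i] for i in rng.integers(0, 20, size=int(rng.integers(10, 40))))
            b = "".join(AA[i] for i in rng.integers(0, 20, size=int(rng.integers(10, 40))))
            assert aligner.score(a, b) == sw_gotoh_score(a, b)

    def test_textbook_pair_found_in_translated_frame(self):
        protein = "HEAGAWGHEE"
        genome = [SequenceRecord("g", back_translate("PAWHEAE"))]
        cfg = TranslatedSearchConfig(evalue_cutoff=1e6)  # report weak hits
        hits = translated_search(protein, genome, cfg)
        assert hits and hits[0].frame == 1
        # engine's best frame score equals the independent DP on that frame
        oracle = sw_gotoh_score("PAWHEAE", protein)
        engine = cfg.aligner().score("PAWHEAE", protein)
        assert engine == oracle

    def test_random_protein_finds_nothing_at_strict_cutoff(self, rng):
        genome = [SequenceRecord("g", random_sequence(rng, 100_000, 0.5))]
        for _ in range(3):
            protein = "".join(AA[i] for i in rng.integers(0, 20, size=100))
            assert translated_search(protein, genome) == []

    def test_illegal_residues_rejected(self, rng):
        genome = [SequenceRecord("g", random_sequence(rng, 1000, 0.5))]
        with pytest.raises(ValueError, match="illegal"):
            translated_search("MKVLJ?AAAA", genome)


def _diverged_protein(rng, protein, keep_fraction):
    out = []
    for aa in protein:
        if rng.random() < keep_fraction:
            out.append(aa)
        else:
            out.append(AA[int(rng.integers(0, 20))])
    return "".join(out)


class TestClassification:
    def test_planted_panel_classes(self, rng):
        """Shared genes are called common, heavily diverged genes
        low_similarity, private genes unique."""
        n_common, n_div, n_priv = 16, 4, 4
        proteins = {}
        target_parts = []
        for i in range(n_common):
            orf = random_coding_sequence(rng, 300, 0.5)
            gid = f"c{i}"
            proteins[gid] = str(Seq(orf).translate())
            target_parts.append(orf)
        for i in range(n_div):
            orf = random_coding_sequence(rng, 360, 0.5)
            prot = str(Seq(orf).translate())
            gid = f"d{i}"
            proteins[gid] = prot
            target_parts.append(back_translate(_diverged_protein(rng, prot, 0.35)))
        for i in range(n_priv):
            orf = random_coding_sequence(rng, 300, 0.5)
            proteins[f"p{i}"] = str(Seq(orf).translate())
        genome = [SequenceRecord("t", random_sequence(rng, 300, 0.5).join(target_parts))]
        calls = {
            c.gene_id: c
            for c in classify_conservation(proteins, genome, threshold_pct=50)
        }
        for i in range(n_common):
            assert calls[f"c{i}"].conservation_class == "common"
        for i in range(n_div):
            assert calls[f"d{i}"].conservation_class == "low_similarity"
            assert calls[f"d{i}"].criterion_value < 50
        for i in range(n_priv):
            assert calls[f"p{i}"].conservation_class == "unique"

    def test_empty_hit_table_all_unique(self):
        calls = classify_conservation({"g1": "M" * 20, "g2": "K" * 20}, hits={})
        assert all(c.conservation_class == "unique" for c in calls)

    def test_threshold_zero_never_low_similarity(self, rng):
        orf = random_coding_sequence(rng, 300, 0.5)
        prot = str(Seq(orf).translate())
        genome = [SequenceRecord("t", back_translate(_diverged_protein(rng, prot, 0.4)))]
        calls = classify_conservation({"g": prot}, genome, threshold_pct=0)
        assert calls[0].conservation_class in ("common", "unique")

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never moves a gene from low_similarity to
        common."""
        orf = random_coding_sequence(rng, 360, 0.5)
        prot = str(Seq(orf).translate())
        genome = [SequenceRecord("t", back_translate(_diverged_protein(rng, prot, 0.6)))]
        classes = []
        for thr in (10, 40, 60, 80, 99):
            calls = classify_conservation({"g": prot}, genome, threshold_pct=thr)
            classes.append(calls[0].conservation_class)
        seen_low = False
        for cls in classes:
            if cls == "low_similarity":
                seen_low = True
            assert not (seen_low and cls == "common")

    def test_symmetric_for_verbatim_gene(self, rng):
        """A gene planted verbatim in both assemblies is common in both
        search directions."""
        orf = random_coding_sequence(rng, 300, 0.5)
        prot = str(Seq(orf).translate())
        a = [SequenceRecord("a", random_sequence(rng, 400, 0.5) + orf)]
        b = [SequenceRecord("b", orf + random_sequence(rng, 400, 0.5))]
        for target in (a, b):
            calls = classify_conservation({"g": prot}, target)
            assert calls[0].conservation_class == "common"


class TestSummary:
    def _calls(self, n_common, n_low, n_unique):
        out = []
        out += [ConservationCall(f"c{i}", "common", None, 90.0) for i in range(n_common)]
        out += [ConservationCall(f"l{i}", "low_similarity", None, 30.0) for i in range(n_low)]
        out += [ConservationCall(f"u{i}", "unique", None, None) for i in range(n_unique)]
        return out

    def test_two_decimal_percentages(self):
        s = summarize_conservation(self._calls(9239, 893, 928))
        assert s.total == 11_060
        assert s.percentages == {"common": 83.54, "low_similarity": 8.07, "unique": 8.39}

    def test_larger_panel_percentage(self):
        s = summarize_conservation(self._calls(10_484, 2_767, 5_395))
        assert s.total == 18_646
        assert s.percentages["common"] == 56.23

    def test_single_class_is_100(self):
        s = summarize_conservation(self._calls(7, 0, 0))
        assert s.percentages["common"] == 100.00

    def test_partition_invariant(self, rng):
        for _ in range(10):
            n = [int(x) for x in rng.integers(0, 50, size=3)]
            if sum(n) == 0:
                continue
            s = summarize_conservation(self._calls(*n))
            assert sum(s.counts.values()) == s.total == sum(n)
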