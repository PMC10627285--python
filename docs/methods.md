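# Methods

This note documents the models and procedures implemented in
`karyoscan`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical conventions used
throughout.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 (1-based
inclusive) is converted at the I/O boundary; blast-style hit records
keep their native 1-based inclusive convention with `t_start > t_end`
encoding a minus-strand hit. Parsers report errors with file and line
number, and duplicate sequence ids are an error rather than a silent
overwrite, because every downstream join keys on id. N bases count as
mismatches in alignment-like comparisons and are excluded from the
denominator of GC content.

Percentages in summaries are rounded half-away-from-zero to the stated
number of decimals (`core.percent`). This convention reproduces, for
example, 9,239/11,060 → 83.54 and 733/758 → 96.7.

## Telomere scanning

A telomeric array at a 5' end is a pair (s, t): start s within
`end_window` (default 1,000 bp) of the terminus and total length t with
t ≥ `min_copies`·|unit| (default 5 copies of `CCCTAA`), valid when the
Hamming distance between the spanned sequence and the tiled unit is at
most `max_mismatch_fraction`·t (default 0.1). Among valid arrays the
longest wins; ties prefer fewer mismatches, then proximity to the
terminus. Both the unit and its reverse complement are tried, and the
3' end is scanned by applying the 5' scanner to the reverse complement
and mapping coordinates back — this makes reverse-complement symmetry
of the detector exact by construction. Fractional copies are reported
to one decimal. Arrays longer than `max_array_length` (20 kb) are not
considered; real telomeric arrays are far shorter.

The published analyses located telomeres with an exact-matching
nucleotide search of five tandem units; a native tandem-array scanner
with an explicit mismatch budget replaces it here. The default 10%
budget is deliberately slightly permissive; with it, a maximal array may
extend a few bases past a planted exact array into flanking sequence
(the extension keeps the overall mismatch fraction within budget), so
exact copy-number assertions should set the budget to 0. Both knobs are
exposed. Monotonicity holds: raising `min_copies` or lowering the
mismatch budget never creates hits.

## Windowed profiles and enriched regions

GC and repeat-density profiles tile each sequence with fixed windows
(defaults: 50 kb for GC and LTR-class density, 5 kb for LINE-class
density). The trailing partial window is emitted with its true length
so that Σ value·length equals the total merged masked length exactly;
overlapping repeat annotations are merged first so densities never
exceed 1. A window containing no unambiguous base yields a missing GC
value rather than zero.

Enriched regions are maximal runs of at least `min_windows` consecutive
windows with value strictly above the threshold (default 0.5, matching
the ">50% of a 5-kb interval" convention used to flag
centromere-candidate repeat concentrations). A run whose midpoint lies
in the middle third of the chromosome is classified `center_third`,
otherwise `terminal_third`; "thirds" is an explicit formalization of
"near the center or the end", and the threshold is configurable.

## Terminal-overlap circularization

For a linearized circular molecule the detector finds the maximal
prefix length L ≥ `min_overlap` (default 1,000 bp, guarding against
short spurious terminal repeats) whose match to the length-L suffix
reaches `min_identity`. At identity 1.0 this is the longest border of
the string, computed with the KMP prefix function in O(n); the
quadratic all-candidates scan is kept as the test oracle. For
min_identity < 1 the largest qualifying L is taken by scanning lengths
in descending order. Trimming removes the suffix copy; idempotence
(re-detection finds nothing, also after rotating the sequence) is the
circularity check. The default identity of 1.0 mirrors the
perfectly-matching duplication that motivates the operation; the
sub-identity mode exists for assemblies with residual consensus errors.

## Translated search and conservation classes

The conservation stage is a desk-scale equivalent of a translated
protein-vs-genome search: each protein is aligned locally against all
six reading frames (standard genetic code, N-containing codons → X,
stops rendered `*`) with the BLOSUM62 matrix and affine gaps (open 11,
extend 1, so a gap of length k costs 11 + k). There is no heuristic
seeding — the full Smith–Waterman is affordable at the genome sizes
this package targets, and an external blast-tab file can be supplied
for larger problems with identical best-hit semantics. E-values use
the Karlin–Altschul form E = K·m·n·e^(−λS) with published ungapped
BLOSUM62 constants (λ = 0.3176, K = 0.134). E-values act purely as a
reporting threshold (default 1.0e−10); tests pin score-level behavior
against an independent quadratic Smith–Waterman–Gotoh oracle rather
than E-values themselves.

Genes are partitioned three ways against the other assembly: `unique`
(no hit at E ≤ cutoff), `low_similarity` (best hit below the 50%
threshold), `common` (otherwise). The best hit is the highest bit
score, ties broken by lower E-value, then lower target coordinate. The
classification criterion defaults to percent identity;
`criterion="similarity"` (positive-scoring columns) is available
because published "similarities/identities" phrasing does not fix the
choice. Frameshift-spanning genes are not stitched across frames; the
best single HSP decides the call.

## Depth, gene coverage, and clade clustering

Depth matrices count, per reference position, the placements covering
it (clipped to bounds; unmapped placements ignored; each mapped
placement counts once — duplicate/secondary distinctions are not
modeled). Gene coverage is the fraction of a gene's positions at depth
≥ `min_depth` (default 3), a presence signal robust to uneven coverage.
The mapping rate is simply mapped/total placements and is undefined for
zero reads.

For clade analysis, per-sample coverage rows over two references are
concatenated with namespaced gene columns — genes present in only one
reference keep their columns, and that asymmetry is exactly the signal
that separates clades. Samples are clustered agglomeratively on
Euclidean distance with complete linkage (the default of R's `heatmap`,
the tool this kind of coverage clustering is conventionally done with);
average and single linkage are available. Rows are sorted by name before clustering so results
are order-invariant, and the dendrogram is exported as Newick.

## Synteny anchors, chimeras, inversions

Anchors are built only from genes with zero repeat overlap (the
`nonrepetitive_genes` selector; a maximum-overlap-fraction mode exists
because "genes within nonrepetitive regions" can reasonably be read
either way). Each gene contributes at most one anchor — its best
translated hit — which by itself suppresses the multi-locus matches
that dispersed repeats would otherwise produce.

Correspondence labels per query chromosome: `one_to_one` when the top
target holds ≥ 0.8 of anchors; `chimeric` when the top two targets each
hold ≥ 0.25 and jointly ≥ 0.8; otherwise `dispersed`. These thresholds
formalize a narrative description ("matched approximately half of two
chromosomes") and are configuration, not constants.

Blocks are built per query chromosome by greedy chaining of
query-ordered anchors into maximal runs monotone in target coordinate,
tolerating up to `max_gap_anchors` (default 2) consecutive outliers;
accumulated outliers seed the next block, which resolves an inversion
boundary to within one anchor. Inverted blocks with ≥
`min_block_anchors` (default 5) anchors are called inversions. Greedy
chaining was preferred over optimal chaining for transparency; the
longest-monotone-run behavior is validated on planted rearrangements.

## Synthetic data: what it emulates, what it does not

`simulate_genome` builds chromosomes from GC-biased i.i.d. background
(default GC 0.44, matching a repeat-dense basidiomycete nuclear
genome), plants exact telomere arrays per an explicit per-end plan
(plus-strand unit at 5' ends, reverse complement at 3' ends, 10 copies
by default), inserts non-overlapping diverged copies of repeat-family
consensus sequences until each family's target genome fraction is met
(±10% relative), and places stop-free coding genes in the remaining
free space. All randomness flows from one integer seed; identical spec
+ seed gives byte-identical artifacts. Truth tables (telomere ends,
repeat BED, gene GFF3, coding sequences) always validate against the
emitted FASTA.

`derive_rearranged` applies inversions, translocations, fissions and
fusions sequentially (coordinates refer to the state at application
time; inversions listed on one sequence must not overlap), lifting gene
intervals through every edit and dropping-with-log genes that span a
breakpoint.

`simulate_clade_panel` models a panel of taxa whose gene sets are
core ∪ clade ∪ private (defaults 60/25/15 genes per taxon — stated
proportions are a design default, not an estimate of any real panel).
One reference genome is laid out per designated reference taxon
(defaults: the first taxon of each of the first two clades, mirroring a
two-assembly design). Reads are drawn per present gene with the start
window sized so the mean realized depth over the gene equals
`coverage_depth` (default 10×, read length 100); reads from genes a
reference lacks are emitted unmapped. Consequently the mapping rate
equals the planted shared-gene fraction up to sampling noise. Reads
are placements, not sequences: no sequencing errors, indels, quality
strings, or mapping ambiguity are modeled, and no read mapper is
bundled — passing tests therefore demonstrate the correctness of the
counting, classification and clustering machinery on ideal placements,
not robustness to alignment artifacts in real data. Likewise repeat
insertions are non-nested and genes never overlap repeats, which real
genomes do not guarantee.

## Problem sizes

The bundled demo pipeline and the test suite run on deliberately small
instances chosen to exercise every code path with comfortable margins:
demo chromosomes of 80–120 kb, a 24-kb stand-in for the organelle
circle (the full 122,566 + 15,636 bp geometry is exercised directly in
the circularization tests and the acceptance script), clade panels of
9 taxa × ~100 genes at 10× depth, and synteny instances of ~20 genes.
The algorithms have no size-dependent branches, so behavior at these
sizes is representative.

## Known limitations

- The translated search reports the best local alignment per frame
  (one HSP); genes split across many exons or frameshifts in the target
  are summarized by their strongest segment.
- Chimera/inversion thresholds are formalizations of narrative
  descriptions; different thresholds change labels, not the underlying
  anchor table.
- The enriched-region location classes use chromosome thirds; assemblies
  with large unplaced gaps would need a finer localization model.
- `min_identity < 1` circularization scans candidate lengths
  quadratically in the worst case; it is intended for organelle-scale
  contigs, not chromosomes.
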