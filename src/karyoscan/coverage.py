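"""Read-depth matrices, per-gene coverage, mapping rates, and clade clustering.

This reproduces the coverage arm of the comparative pipeline: read
placements (from the simulator's truth, a minimal SAM, or a placement
TSV) are piled into per-position depth vectors; each gene's coverage is
the fraction of its positions with depth >= 3 (a presence signal); the
per-sample coverage rows over two reference assemblies are concatenated
and clustered hierarchically on Euclidean distance (complete linkage, as
in R's heatmap default), and the dendrogram is cut at k to recover
clades.

No read mapper is bundled; placements are an explicit input, which keeps
this stage independent of any particular aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .core import GenomicInterval

__all__ = [
    "Placement",
    "DepthMatrix",
    "ClusterResult",
    "read_placements_tsv",
    "write_placements_tsv",
    "read_sam_placements",
    "build_depth_matrix",
    "gene_coverage",
    "mapping_rate",
    "combine_and_cluster",
    "cluster_matrix",
]


@dataclass
class Placement:
    """One read placement: 0-based half-open reference span, or unmapped."""

    read_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    mapped: bool = True


@dataclass
class DepthMatrix:
    depths: dict  # seq_id -> np.ndarray of int32 per-position depth

    def __getitem__(self, seq_id: str) -> np.ndarray:
        return self.depths[seq_id]

    def total_depth(self) -> int:
        return int(sum(arr.sum() for arr in self.depths.values()))


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels: dict  # sample -> cluster id (1..k)
    samples: list
    newick: str

    def clusters(self) -> list[frozenset]:
        """Flat clusters as sets of sample names."""
        by_id: dict[int, set] = {}
        for sample, cid in self.labels.items():
            by_id.setdefault(cid, set()).add(sample)
        return [frozenset(s) for s in by_id.values()]


# ---------------------------------------------------------------------------
# Placement I/O


def read_placements_tsv(path) -> list[Placement]:
    """6-column placement table: read_id, seq_id, start, end, strand, mapped."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(f)}")
            mapped = f[5] in ("1", "true", "True", "mapped")
            out.append(
                Placement(f[0], f[1], int(f[2]), int(f[3]), f[4], mapped)
            )
    return out


def write_placements_tsv(placements: Iterable[Placement], path) -> None:
    with open(path, "wt") as fh:
        for p in placements:
            fh.write(
                f"{p.read_id}\t{p.seq_id}\t{p.start}\t{p.end}\t{p.strand}\t"
                f"{1 if p.mapped else 0}\n"
            )


_CIGAR_RE = re.compile(r"(\d+)([MIDS])")


def _cigar_ref_span(cigar: str) -> int:
    """Reference-consumed length of a minimal CIGAR (M/I/D/S only)."""
    span = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ValueError(f"unsupported CIGAR {cigar!r}")
        pos = m.end()
        n, op = int(m.group(1)), m.group(2)
        if op in ("M", "D"):
            span += n
    if pos != len(cigar):
        raise ValueError(f"unsupported CIGAR {cigar!r}")
    return span


def read_sam_placements(path) -> list[Placement]:
    """Minimal SAM reader: QNAME, FLAG (unmapped bit 0x4, strand bit 0x10),
    RNAME, POS, CIGAR with M/I/D/S operations only.  Header lines are
    skipped; no index or binary support."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("@"):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: SAM line has fewer than 6 fields")
            qname, flag_s, rname, pos_s, _mapq, cigar = f[:6]
            flag = int(flag_s)
            if flag & 0x4 or rname == "*":
                out.append(Placement(qname, "*", 0, 0, "+", mapped=False))
                continue
            start = int(pos_s) - 1
            span = _cigar_ref_span(cigar)
            strand = "-" if flag & 0x10 else "+"
            out.append(Placement(qname, rname, start, start + span, strand, True))
    return out


# ---------------------------------------------------------------------------
# Depth and coverage


def build_depth_matrix(
    placements: Iterable[Placement], reference_lengths: Mapping[str, int]
) -> DepthMatrix:
    """Per-position pileup depth from mapped placements.

    Placements are clipped to the reference bounds; unmapped placements
    are ignored; a mapped placement on an unknown sequence is an error.
    """
    deltas = {
        seq_id: np.zeros(length + 1, dtype=np.int32)
        for seq_id, length in reference_lengths.items()
    }
    for p in placements:
        if not p.mapped:
            continue
        if p.seq_id not in deltas:
            raise ValueError(f"placement {p.read_id!r} on unknown sequence {p.seq_id!r}")
        length = reference_lengths[p.seq_id]
        start = max(0, p.start)
        end = min(length, p.end)
        if start >= end:
            continue
        deltas[p.seq_id][start] += 1
        deltas[p.seq_id][end] -= 1
    return DepthMatrix(
        {seq_id: np.cumsum(d[:-1]).astype(np.int32) for seq_id, d in deltas.items()}
    )


def gene_coverage(
    depth: DepthMatrix, genes: Sequence[GenomicInterval], min_depth: int = 3
) -> dict[str, float]:
    """Fraction of each gene's positions covered at >= min_depth reads."""
    out = {}
    for gene in genes:
        if gene.seq_id not in depth.depths:
            raise ValueError(f"gene {gene.name!r} on unknown sequence {gene.seq_id!r}")
        vec = depth.depths[gene.seq_id]
        if gene.end > len(vec):
            raise ValueError(
                f"gene {gene.name!r} extends past end of {gene.seq_id!r}"
            )
        window = vec[gene.start : gene.end]
        out[gene.name or f"{gene.seq_id}:{gene.start}-{gene.end}"] = float(
            (window >= min_depth).mean()
        )
    return out


def mapping_rate(placements: Sequence[Placement]) -> float:
    """Fraction of placements flagged mapped; undefined (error) for none."""
    if not placements:
        raise ValueError("mapping rate of zero reads is undefined")
    return sum(1 for p in placements if p.mapped) / len(placements)


# ---------------------------------------------------------------------------
# Clustering


def _newick(node, names, parent_height: float | None = None) -> str:
    height = node.dist
    length = 0.0 if parent_height is None else parent_height - height
    if node.is_leaf():
        return f"{names[node.id]}:{length:.6g}"
    left = _newick(node.get_left(), names, height)
    right = _newick(node.get_right(), names, height)
    if parent_height is None:
        return f"({left},{right});"
    return f"({left},{right}):{length:.6g}"


def cluster_matrix(
    matrix: pd.DataFrame, k: int, method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of sample rows on Euclidean distance.

    ``matrix`` is samples x features; rows are sorted by sample name
    first so the result is invariant to input order (up to dendrogram
    reflection).
    """
    if matrix.isna().any().any():
        raise ValueError("coverage matrix contains missing values")
    matrix = matrix.sort_index()
    samples = list(matrix.index)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not 1 <= k <= len(samples):
        raise ValueError(f"k={k} out of range for {len(samples)} samples")
    dists = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    z = linkage(dists, method=method)
    flat = fcluster(z, t=k, criterion="maxclust")
    labels = dict(zip(samples, (int(c) for c in flat)))
    newick = _newick(to_tree(z), samples)
    return ClusterResult(z, labels, samples, newick)


def combine_and_cluster(
    coverage_by_reference: Mapping[str, pd.DataFrame],
    k: int,
    method: str = "complete",
) -> tuple[pd.DataFrame, ClusterResult]:
    """Concatenate per-reference gene-coverage matrices and cluster samples.

    ``coverage_by_reference`` maps a reference name to a samples x genes
    DataFrame.  Gene columns are namespaced ``reference::gene`` so the
    combined matrix keeps the two references' gene spaces disjoint --
    the asymmetry of genes present in only one reference is exactly the
    signal that separates clades.  Every sample must have a row for
    every reference, with identical columns across samples.
    """
    frames = []
    sample_sets = []
    for ref_name in sorted(coverage_by_reference):
        df = coverage_by_reference[ref_name].copy()
        df.columns = [f"{ref_name}::{c}" for c in df.columns]
        frames.append(df.sort_index())
        sample_sets.append(set(df.index))
    if not frames:
        raise ValueError("no coverage matrices supplied")
    if any(s != sample_sets[0] for s in sample_sets[1:]):
        raise ValueError("samples differ across references")
    combined = pd.concat(frames, axis=1)
    return combined, cluster_matrix(combined, k, method)
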