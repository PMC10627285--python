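"""Readers and writers for FASTA, BED, GFF3, placement tables and hit tables.

All parse errors carry the offending line number.  Plain and gzip inputs
are accepted everywhere.  Internally everything is 0-based half-open;
GFF3 (1-based inclusive) is converted on read and on write.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Sequence

from .core import DNA_ALPHABET, GenomicInterval, HitRecord, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_hits",
    "write_hits",
]


class FormatError(ValueError):
    """Malformed input file; message names the file and line."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into records, in file order.

    Wrapped sequence lines are concatenated and lowercase is normalized
    to uppercase.  Duplicate ids, characters outside ACGTN, and sequence
    data before the first header are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id = None
    cur_desc = ""
    cur_chunks: list[str] = []

    def _flush():
        if cur_id is None:
            return
        records.append(SequenceRecord(cur_id, "".join(cur_chunks), cur_desc))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate record id {cur_id!r}")
                seen.add(cur_id)
                cur_chunks = []
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                bad = set(line.upper()) - DNA_ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
                    )
                cur_chunks.append(line.upper())
    _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3-6 into intervals (already 0-based half-open)."""
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            seq_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: invalid BED interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(seq_id, start, end, strand, name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


_GFF_KIND = {"gene": "gene", "mRNA": "gene", "CDS": "gene"}


def read_gff3(path, feature_types: Sequence[str] | None = None) -> list[GenomicInterval]:
    """Read GFF3 features into 0-based half-open intervals.

    The GFF3 feature type is recorded in ``attrs['feature_type']`` and
    mapped onto the internal ``kind`` vocabulary where possible.  If
    ``feature_types`` is given, only those types are kept.
    """
    out: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(fields)} columns, expected 9")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer GFF3 coordinate") from exc
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: invalid GFF3 interval {start1}-{end1}"
                )
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = {"feature_type": ftype}
            name = ""
            for pair in attr_s.split(";"):
                pair = pair.strip()
                if not pair or "=" not in pair:
                    continue
                key, val = pair.split("=", 1)
                attrs[key] = val
            name = attrs.get("ID") or attrs.get("Name") or ""
            out.append(
                GenomicInterval(
                    seq_id, start, end, strand, name,
                    kind=_GFF_KIND.get(ftype, "other"), attrs=attrs,
                )
            )
    return out


def write_gff3(intervals: Iterable[GenomicInterval], path, source: str = "karyoscan") -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            ftype = iv.attrs.get("feature_type", iv.kind if iv.kind != "other" else "region")
            attrs = [f"ID={iv.name}"] if iv.name else []
            for key, val in iv.attrs.items():
                if key in ("feature_type", "ID"):
                    continue
                attrs.append(f"{key}={val}")
            fh.write(
                f"{iv.seq_id}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{';'.join(attrs) or '.'}\n"
            )


def read_intervals(path, dialect: str) -> list[GenomicInterval]:
    """Dispatch to the BED or GFF3 reader; unknown dialects are rejected."""
    if dialect.upper() == "BED":
        return read_bed(path)
    if dialect.upper() == "GFF3":
        return read_gff3(path)
    raise ValueError(f"unknown interval dialect {dialect!r} (expected BED or GFF3)")


# ---------------------------------------------------------------------------
# Hit tables (blast outfmt-6 field order, with two appended columns
# pct_similarity and frame when produced internally)

_HIT_COLUMNS = (
    "query_id target_seq pct_identity aln_len mismatches gap_opens "
    "q_start q_end t_start t_end e_value bit_score"
).split()


def read_hits(path) -> list[HitRecord]:
    """Read a 12-column blast-tab file (optionally with pct_similarity and
    frame appended as columns 13-14)."""
    out: list[HitRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: hit line has {len(f)} columns, expected >= 12")
            try:
                pct_id = float(f[2])
                pct_sim = float(f[12]) if len(f) > 12 else pct_id
                frame = int(f[13]) if len(f) > 13 else 0
                out.append(
                    HitRecord(
                        query_id=f[0],
                        target_seq=f[1],
                        pct_identity=pct_id,
                        aln_len=int(f[3]),
                        q_start=int(f[6]),
                        q_end=int(f[7]),
                        t_start=int(f[8]),
                        t_end=int(f[9]),
                        e_value=float(f[10]),
                        bit_score=float(f[11]),
                        pct_similarity=pct_sim,
                        frame=frame,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_hits(hits: Iterable[HitRecord], path) -> None:
    with open(path, "wt") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.target_seq, f"{h.pct_identity:.2f}", h.aln_len,
                        0, 0, h.q_start, h.q_end, h.t_start, h.t_end,
                        f"{h.e_value:.3g}", f"{h.bit_score:.1f}",
                        f"{h.pct_similarity:.2f}", h.frame,
                    )
                )
                + "\n"
            )
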