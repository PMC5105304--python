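"""On-disk formats: FASTA, FASTQ, BED, GFF3, and tab-separated tables.

Conventions: in-memory coordinates are 1-based inclusive everywhere; BED
is written/read as 0-based half-open (the conversion happens only here).
Structured text errors raise :class:`FormatError` with the offending line
number.
"""

from __future__ import annotations

import csv
import tempfile
from dataclasses import asdict, fields
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import ReadAlignment
from .annotate import GeneModel
from .errors import FormatError, InvariantError
from .genome import CnLohSegment, Haplotype, L1Copy, TruthInsertion
from .simulate import Read, ReadSet

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_bed",
    "read_bed",
    "write_gff",
    "read_gff",
    "write_segments_tsv",
    "read_segments_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_alignments_tsv",
    "read_alignments_tsv",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path: PathLike, chroms: Haplotype, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(chroms[name]), id=name, description="") for name in sorted(chroms)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: PathLike) -> Haplotype:
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except ValueError as exc:
        raise FormatError(f"{path}: invalid FASTA: {exc}") from exc


def write_fastq(path: PathLike, reads: ReadSet) -> None:
    """Write a read set; paired reads are interleaved with /1 and /2 suffixes."""
    with open(path, "w") as fh:
        for r in reads.reads:
            if r.mate_sequence is None:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            else:
                fh.write(f"@{r.id}/1\n{r.sequence}\n+\n{r.quality}\n")
                fh.write(f"@{r.id}/2\n{r.mate_sequence}\n+\n{r.mate_quality}\n")


def read_fastq(path: PathLike) -> List[Tuple[str, str, str]]:
    """Read (id, sequence, quality) tuples; no pairing is reconstructed."""
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: FASTQ record count is not a multiple of 4")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise FormatError(f"{path} line {i + 1}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path} line {i + 3}: FASTQ separator must start with '+'")
        if len(seq) != len(qual):
            raise FormatError(f"{path} line {i + 2}: sequence/quality length mismatch")
        out.append((header[1:].split()[0], seq, qual))
    return out


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk, 1-based inclusive in memory)


def write_bed(
    path: PathLike,
    intervals: Iterable[Union[L1Copy, Tuple]],
) -> None:
    """Intervals are L1Copy or (chrom, start1, end1[, name[, strand]]) tuples."""
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, L1Copy):
                chrom, start, end, name, strand = item.chrom, item.start, item.end, "L1", item.strand
            else:
                chrom, start, end = item[0], int(item[1]), int(item[2])
                name = item[3] if len(item) > 3 else "."
                strand = item[4] if len(item) > 4 else "."
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")


def read_bed(path: PathLike) -> List[Tuple[str, int, int, str, str]]:
    """(chrom, start1, end1, name, strand) tuples, 1-based inclusive."""
    out = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {n}: BED needs >= 3 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path} line {n}: non-integer BED coordinate") from exc
            if start0 < 0 or end0 <= start0:
                raise FormatError(f"{path} line {n}: invalid BED interval")
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append((parts[0], start0 + 1, end0, name, strand))
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff(path: PathLike, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.name)):
            fh.write(
                f"{g.chrom}\tpreset\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID=gene:{g.name};Name={g.name}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tpreset\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID=exon:{g.name}.{i};Parent=gene:{g.name}\n"
                )


def read_gff(path: PathLike) -> List[GeneModel]:
    import gffutils

    with open(path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: invalid GFF3: {exc}") from exc
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted((e.start, e.end) for e in db.children(g, featuretype="exon"))
        )
        genes.append(
            GeneModel(
                name=g.attributes.get("Name", [g.id])[0],
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=exons,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# TSV tables


def _write_tsv(path: PathLike, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _read_tsv(path: PathLike, expected_header: Sequence[str]) -> List[Dict[str, str]]:
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path} line 1: empty table") from None
        if header != list(expected_header):
            raise FormatError(
                f"{path} line 1: header {header!r} != expected {list(expected_header)!r}"
            )
        rows = []
        for n, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(f"{path} line {n}: expected {len(header)} columns")
            rows.append(dict(zip(header, row)))
    return rows


_SEGMENT_COLS = ("chrom", "start", "end", "copy_number", "loh")


def write_segments_tsv(path: PathLike, segments: Sequence[CnLohSegment]) -> None:
    _write_tsv(
        path,
        _SEGMENT_COLS,
        [
            (s.chrom, s.start, s.end, s.copy_number, "Y" if s.loh else "N")
            for s in sorted(segments, key=lambda s: (s.chrom, s.start))
        ],
    )


def read_segments_tsv(path: PathLike) -> List[CnLohSegment]:
    out = []
    for n, row in enumerate(_read_tsv(path, _SEGMENT_COLS), start=2):
        try:
            out.append(
                CnLohSegment(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    copy_number=int(row["copy_number"]),
                    loh=row["loh"] == "Y",
                )
            )
        except (ValueError, InvariantError) as exc:
            raise FormatError(f"{path} line {n}: {exc}") from exc
    return out


_TRUTH_COLS = (
    "sample_id", "chrom", "junction5", "junction3", "strand",
    "element_length", "inversion_length", "polya_length", "tsd_length",
    "somatic", "blood_only_loss", "gene", "cn", "loh",
    "partially_specified", "haplotype",
)


def write_truth_tsv(path: PathLike, truth: Sequence[TruthInsertion]) -> None:
    _write_tsv(
        path,
        _TRUTH_COLS,
        [
            (
                t.sample_id, t.chrom, t.junction5, t.junction3, t.strand,
                t.element_length, t.inversion_length, t.polya_length, t.tsd_length,
                int(t.somatic), int(t.blood_only_loss), t.gene, t.cn, t.loh,
                int(t.partially_specified), t.haplotype,
            )
            for t in truth
        ],
    )


def read_truth_tsv(path: PathLike) -> List[TruthInsertion]:
    out = []
    for n, row in enumerate(_read_tsv(path, _TRUTH_COLS), start=2):
        try:
            out.append(
                TruthInsertion(
                    chrom=row["chrom"],
                    junction5=int(row["junction5"]),
                    junction3=int(row["junction3"]),
                    strand=row["strand"],
                    element_length=int(row["element_length"]),
                    inversion_length=int(row["inversion_length"]),
                    polya_length=int(row["polya_length"]),
                    tsd_length=int(row["tsd_length"]),
                    somatic=bool(int(row["somatic"])),
                    blood_only_loss=bool(int(row["blood_only_loss"])),
                    sample_id=row["sample_id"],
                    gene=row["gene"],
                    cn=row["cn"],
                    loh=row["loh"],
                    partially_specified=bool(int(row["partially_specified"])),
                    haplotype=row["haplotype"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {n}: {exc}") from exc
    return out


_ALIGN_COLS = ("read_id", "chrom", "start", "end", "strand", "mismatches", "status")


def write_alignments_tsv(path: PathLike, alignments: Sequence[ReadAlignment]) -> None:
    def dot(x):
        return "." if x is None else x

    _write_tsv(
        path,
        _ALIGN_COLS,
        [
            (a.read_id, dot(a.chrom), dot(a.start), dot(a.end), dot(a.strand),
             dot(a.mismatches), a.status)
            for a in alignments
        ],
    )


def read_alignments_tsv(path: PathLike) -> List[ReadAlignment]:
    out = []
    for n, row in enumerate(_read_tsv(path, _ALIGN_COLS), start=2):
        try:
            unmapped = row["status"] == "unmapped"
            out.append(
                ReadAlignment(
                    read_id=row["read_id"],
                    chrom=None if unmapped else row["chrom"],
                    start=None if unmapped else int(row["start"]),
                    end=None if unmapped else int(row["end"]),
                    strand=None if unmapped else row["strand"],
                    mismatches=None if unmapped else int(row["mismatches"]),
                    status=row["status"],
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {n}: {exc}") from exc
    return out
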