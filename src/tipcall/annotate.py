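"""Hallmark annotation of validated L1 insertions.

Target-primed reverse transcription (TPRT) leaves a characteristic
signature at an integration site: a short target-site duplication (TSD)
flanking the element, an intact 3' end with a polyA tail, frequent 5'
truncation, and (via twin priming) an optional inversion of the 5'-most
retained segment. This module measures those hallmarks from sequence:
given the inserted-allele sequence and the empty-site flanks it recovers
(strand, element length, inversion length, polyA length, TSD length), and
it places insertions into gene context.

Coordinates are 1-based inclusive throughout, converted to/from 0-based
half-open only at on-disk (BED) boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .consensus import L1Consensus, revcomp
from .errors import InvariantError, NotL1InsertionError

__all__ = [
    "measure_tsd",
    "characterize_insertion",
    "InsertionParse",
    "GeneModel",
    "GeneContext",
    "gene_overlap",
    "AnnotatedInsertion",
    "render_report",
]


def measure_tsd(junction5: int, junction3: int) -> int:
    """TSD length from the two junction coordinates.

    Both junction coordinates lie inside the duplicated interval, so the
    duplication spans |junction5 - junction3| + 1 bases. This is the only
    convention consistent with every fully sequenced validated insertion.
    """
    if junction5 <= 0 or junction3 <= 0:
        raise InvariantError("junction coordinates must be positive")
    return abs(junction5 - junction3) + 1


# ---------------------------------------------------------------------------
# allele parsing


@dataclass(frozen=True)
class InsertionParse:
    """Canonical parse of an inserted allele."""

    strand: str
    element_length: int
    inversion_length: int
    polya_length: int
    tsd_length: int
    # 1-based inclusive endpoints of the duplicated interval in the
    # empty-site (pre-insertion) coordinate system of flank5+flank3.
    tsd_start: int
    tsd_end: int


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def _run_len(seq: str, base: str, from_end: bool) -> int:
    n = 0
    it = reversed(seq) if from_end else iter(seq)
    for c in it:
        if c != base:
            break
        n += 1
    return n


def _match_element(element: str, cons: L1Consensus, min_element: int) -> Optional[tuple]:
    """Match an element body against the consensus, allowing a 5' inversion.

    Returns (element_length, inversion_length) or None. The non-inverted
    part must be an exact suffix of the consensus; any remaining 5' part
    must be the reverse complement of the consensus segment immediately
    5' of it (the twin-priming geometry).
    """
    L = len(element)
    if L < min_element or L > len(cons):
        return None
    seq = cons.sequence
    m_raw = min(_common_suffix_len(element, seq), L)
    start = len(seq) - L
    for m in range(m_raw, 0, -1):
        v = L - m
        if v == 0:
            return (L, 0)
        if revcomp(element[:v]) == seq[start : start + v]:
            return (L, v)
    return None


def characterize_insertion(
    allele_sequence: str,
    flank5: str,
    flank3: str,
    l1_consensus: L1Consensus,
    polya_min: int = 5,
    max_tsd: int = 60,
    min_element: int = 30,
) -> InsertionParse:
    """Recover TPRT hallmarks from an inserted allele.

    ``allele_sequence`` is the post-insertion locus and ``flank5 + flank3``
    the pre-insertion (empty site) locus; the split between the two flanks
    is immaterial because every indel placement of the insert is
    enumerated. For each placement, the TSD is the longest exact
    duplication between the insert's 3' end and the adjacent upstream
    sequence; the polyA tail is the terminal mononucleotide run in element
    orientation (>= ``polya_min``); the remainder must match the consensus
    3' end exactly, with an optional reverse-complemented 5' segment
    (inversion). Among valid parses the canonical one maximizes
    (element length, polyA length, TSD length).
    """
    empty = flank5 + flank3
    ins_len = len(allele_sequence) - len(empty)
    if ins_len <= 0:
        raise NotL1InsertionError("allele is not longer than the empty site")
    f = _common_prefix_len(allele_sequence, empty)
    g = _common_suffix_len(allele_sequence, empty)
    i_max = min(f, len(empty))
    i_min = max(0, len(empty) - g)

    parses: list[InsertionParse] = []
    for i in range(i_max, i_min - 1, -1):
        flank_l = empty[:i]
        mid = allele_sequence[i : i + ins_len]
        t = min(_common_suffix_len(mid, flank_l), max_tsd, ins_len - 1)
        core = mid[: ins_len - t] if t else mid
        for strand in ("+", "-"):
            if strand == "+":
                run = _run_len(core, "A", from_end=True)
                if run < polya_min:
                    continue
                element = core[:-run]
            else:
                run = _run_len(core, "T", from_end=False)
                if run < polya_min:
                    continue
                element = revcomp(core[run:])
            hit = _match_element(element, l1_consensus, min_element)
            if hit is None:
                continue
            length, inv = hit
            parses.append(
                InsertionParse(
                    strand=strand,
                    element_length=length,
                    inversion_length=inv,
                    polya_length=run,
                    tsd_length=t,
                    tsd_start=i - t + 1,
                    tsd_end=i,
                )
            )
    if not parses:
        raise NotL1InsertionError(
            "not an L1 insertion: no parse with an exact consensus 3' match"
        )
    return max(
        parses,
        key=lambda p: (p.element_length, p.polya_length, p.tsd_length),
    )


# ---------------------------------------------------------------------------
# gene context


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure; coordinates 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple = ()

    def __post_init__(self):
        if self.start > self.end:
            raise InvariantError(f"gene {self.name}: start > end")
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise InvariantError(f"gene {self.name}: exon outside gene body")


@dataclass(frozen=True)
class GeneContext:
    gene: str
    feature: str  # intron | exon | intergenic
    distance: int = 0  # distance to nearest gene when intergenic


def gene_overlap(
    chrom: str, position: int, genes: Sequence[GeneModel]
) -> GeneContext:
    """Classify a position as exonic, intronic or intergenic."""
    best: Optional[GeneContext] = None
    nearest = None
    for gene in genes:
        if gene.chrom != chrom:
            continue
        if gene.start <= position <= gene.end:
            tree = IntervalTree.from_tuples((s, e + 1) for s, e in gene.exons) if gene.exons else IntervalTree()
            feature = "exon" if tree.overlaps(position) else "intron"
            ctx = GeneContext(gene=gene.name, feature=feature)
            # exon context wins over intron if genes overlap
            if best is None or (feature == "exon" and best.feature != "exon"):
                best = ctx
        else:
            d = gene.start - position if position < gene.start else position - gene.end
            if nearest is None or d < nearest[0]:
                nearest = (d, gene.name)
    if best is not None:
        return best
    if nearest is not None:
        return GeneContext(gene=nearest[1], feature="intergenic", distance=nearest[0])
    return GeneContext(gene=".", feature="intergenic", distance=-1)


# ---------------------------------------------------------------------------
# report


@dataclass
class AnnotatedInsertion:
    """One validated insertion with its full annotation (one report row)."""

    sample_id: str
    chrom: str
    junction5: int
    junction3: int
    strand: str
    element_length: Optional[int]
    inversion_length: Optional[int]
    polya_length: Optional[int]
    tsd_length: Optional[int]
    gene: str = "."
    feature: str = "intergenic"
    cn: str = "NT"
    loh: str = "NT"
    somatic: bool = False
    partially_specified: bool = False

    def __post_init__(self):
        if (
            not self.partially_specified
            and self.tsd_length is not None
            and measure_tsd(self.junction5, self.junction3) != self.tsd_length
        ):
            raise InvariantError("tsd_length != |junction5 - junction3| + 1")


REPORT_COLUMNS = [
    "sample_id",
    "chromosome",
    "junction5",
    "junction3",
    "strand",
    "element_length_bp",
    "tsd_length_bp",
    "inversion_length_bp",
    "polya_length_bp",
    "gene",
    "feature",
    "cn",
    "loh",
    "section",
]


def render_report(annotated: Iterable[AnnotatedInsertion]) -> pd.DataFrame:
    """Validated-insertion table with blood- and tumor-specific sections."""

    def dot(x):
        return "." if x is None else x

    rows = []
    for a in annotated:
        rows.append(
            {
                "sample_id": a.sample_id,
                "chromosome": a.chrom,
                "junction5": dot(a.junction5),
                "junction3": dot(a.junction3),
                "strand": a.strand,
                "element_length_bp": dot(a.element_length),
                "tsd_length_bp": dot(a.tsd_length),
                "inversion_length_bp": dot(a.inversion_length),
                "polya_length_bp": dot(a.polya_length),
                "gene": a.gene,
                "feature": a.feature,
                "cn": a.cn,
                "loh": a.loh,
                "section": "tumor_specific" if a.somatic else "blood_specific",
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["section", "sample_id", "chromosome", "junction3"],
            key=lambda s: s.astype(str),
            kind="mergesort",
        ).reset_index(drop=True)
    return frame
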