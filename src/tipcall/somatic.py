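"""Tumor-normal comparison, in-silico spanning validation, CN/LOH intersection.

Candidate insertions from the matched samples of one patient are compared
in both directions: a call is shared when the other sample has a call
within a small window, otherwise it is tumor-only or normal-only.
Discordant calls are validated by an in-silico analog of the spanning-PCR
assay: unique exact-match primer anchors are picked on both sides of the
locus and product sizes are computed on every haplotype of both samples -
a productive validation shows the insertion-bearing (filled-site) product
in the call's own sample and only the empty-site product in the other.
Normal-only calls are finally annotated with the tumor copy-number / LOH
segment covering them, the signature of a germline insertion lost from
the tumor genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .errors import InvariantError
from .genome import CnLohSegment, Haplotype, validate_segments
from .scoring import CandidateCall

__all__ = [
    "DiscordantCall",
    "ValidationResult",
    "compare_call_sets",
    "insilico_validate",
    "integrate_cn_loh",
]


@dataclass
class ValidationResult:
    verdict: str  # productive | unproductive | untested
    empty_size: Optional[int] = None
    blood_sizes: Tuple[int, ...] = ()
    tumor_sizes: Tuple[int, ...] = ()
    note: str = ""


@dataclass
class DiscordantCall:
    direction: str  # tumor_only | normal_only
    candidate: CandidateCall
    validation: str = "untested"
    cn: str = "NT"
    loh: str = "NT"
    result: Optional[ValidationResult] = None


def compare_call_sets(
    tumor_calls: Sequence[CandidateCall],
    normal_calls: Sequence[CandidateCall],
    window: int = 200,
) -> Tuple[List[CandidateCall], List[CandidateCall], List[CandidateCall]]:
    """Partition calls into (tumor_only, normal_only, shared).

    A call is shared when the other sample has a call on the same
    chromosome whose junction boundary lies within ``window`` bp. The
    relation is symmetric, so the partition is disjoint and exhaustive.
    """

    def near(call: CandidateCall, others: Sequence[CandidateCall]) -> bool:
        return any(
            o.peak.chrom == call.peak.chrom and abs(o.boundary - call.boundary) <= window
            for o in others
        )

    tumor_only = [c for c in tumor_calls if not near(c, normal_calls)]
    normal_only = [c for c in normal_calls if not near(c, tumor_calls)]
    shared = [c for c in tumor_calls if near(c, normal_calls)] + [
        c for c in normal_calls if near(c, tumor_calls)
    ]
    return tumor_only, normal_only, shared


def _find_unique(seq_by_chrom: Haplotype, probe: str) -> Optional[Tuple[str, int]]:
    """Locate a probe occurring exactly once genome-wide; 0-based position."""
    hit = None
    for chrom in sorted(seq_by_chrom):
        seq = seq_by_chrom[chrom]
        i = seq.find(probe)
        while i != -1:
            if hit is not None:
                return None
            hit = (chrom, i)
            i = seq.find(probe, i + 1)
    return hit


def _pick_primer(
    reference: Haplotype,
    chrom: str,
    anchor: int,
    direction: int,
    primer_flank: int,
    offsets: Tuple[int, int],
) -> Optional[Tuple[int, str]]:
    """A unique exact primer_flank-mer on one side of the locus.

    ``direction`` -1 picks upstream (primer end <= anchor - offsets[0]),
    +1 downstream. Returns (0-based start in reference, sequence).
    """
    seq = reference[chrom]
    for off in range(offsets[0], offsets[1]):
        if direction < 0:
            start = anchor - off - primer_flank
        else:
            start = anchor + off
        if start < 0 or start + primer_flank > len(seq):
            continue
        probe = seq[start : start + primer_flank]
        if "N" in probe:
            continue
        hit = _find_unique(reference, probe)
        if hit == (chrom, start):
            return start, probe
    return None


def _product_sizes(
    haplotypes: Sequence[Haplotype],
    chrom_hint: str,
    left: str,
    right: str,
    max_amplicon: int,
) -> Tuple[int, ...]:
    sizes = []
    for hap in haplotypes:
        lhit = _find_unique(hap, left)
        rhit = _find_unique(hap, right)
        if lhit is None or rhit is None or lhit[0] != rhit[0]:
            continue
        size = rhit[1] + len(right) - lhit[1]
        if 0 < size <= max_amplicon:
            sizes.append(size)
    return tuple(sorted(set(sizes)))


def insilico_validate(
    call,
    blood_haplotypes: Sequence[Haplotype],
    tumor_haplotypes: Sequence[Haplotype],
    reference: Haplotype,
    direction: str = "normal_only",
    primer_flank: int = 20,
    max_amplicon: int = 10_000,
    offsets: Tuple[int, int] = (200, 450),
    min_insert: int = 50,
) -> ValidationResult:
    """In-silico spanning amplification across a putative insertion locus.

    ``call`` needs ``peak`` and ``boundary`` attributes (a CandidateCall).
    Productive means the filled-site product (empty size + >= ``min_insert``)
    appears in the sample the call came from and not in the other.
    """
    chrom = call.peak.chrom
    anchor = call.boundary
    left = _pick_primer(reference, chrom, anchor, -1, primer_flank, offsets)
    right = _pick_primer(reference, chrom, anchor, +1, primer_flank, offsets)
    if left is None or right is None:
        return ValidationResult(verdict="untested", note="no unique primer anchor in search radius")
    lseq, rseq = left[1], right[1]
    empty = right[0] + primer_flank - left[0]
    blood_sizes = _product_sizes(blood_haplotypes, chrom, lseq, rseq, max_amplicon)
    tumor_sizes = _product_sizes(tumor_haplotypes, chrom, lseq, rseq, max_amplicon)

    def filled(sizes: Tuple[int, ...]) -> bool:
        return any(s >= empty + min_insert for s in sizes)

    own, other = (
        (tumor_sizes, blood_sizes) if direction == "tumor_only" else (blood_sizes, tumor_sizes)
    )
    verdict = "productive" if filled(own) and not filled(other) else "unproductive"
    return ValidationResult(
        verdict=verdict,
        empty_size=empty,
        blood_sizes=blood_sizes,
        tumor_sizes=tumor_sizes,
    )


def integrate_cn_loh(
    normal_only_calls: Sequence[DiscordantCall],
    segments: Sequence[CnLohSegment],
) -> List[DiscordantCall]:
    """Annotate normal-only calls with the covering tumor CN/LOH segment."""
    validate_segments(segments)
    trees: Dict[str, IntervalTree] = {}
    for s in segments:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end + 1, s)
    for call in normal_only_calls:
        if call.direction != "normal_only":
            continue
        tree = trees.get(call.candidate.peak.chrom)
        hits = sorted(tree[call.candidate.boundary]) if tree is not None else []
        if hits:
            seg: CnLohSegment = hits[0].data
            call.cn = str(seg.copy_number)
            call.loh = "Y" if seg.loh else "N"
        else:
            call.cn = "NT"
            call.loh = "NT"
    return list(normal_only_calls)
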