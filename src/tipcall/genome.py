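"""Synthetic reference genomes, L1 implantation, and tumor CN/LOH events.

A haplotype is a plain ``dict`` mapping chromosome name to sequence.
Patients are modeled as diploid: each sample (blood, tumor) carries two
haplotypes built from a shared per-patient reference. Heterozygous
insertions live on haplotype B; loss-of-heterozygosity in the tumor is
realized by rebuilding the tumor's carrier haplotype without the
insertions that fall inside an LOH/deletion segment — exactly the event
that makes a germline insertion visible in blood but not in tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import annotate as _annotate
from .consensus import L1Consensus, default_consensus, revcomp
from .errors import InvariantError, PlacementError, SiteIncompatibleError
from .rng import substream

Haplotype = Dict[str, str]

__all__ = [
    "TruthInsertion",
    "L1Copy",
    "ReferenceGenome",
    "CnLohSegment",
    "PatientPair",
    "build_reference",
    "build_element",
    "build_allele",
    "implant_insertion",
    "implant_insertions",
    "build_sample_haplotypes",
    "apply_cn_loh",
    "validate_segments",
]

FIXED_L1_POLYA = 20  # residual polyA retained on annotated genomic copies


@dataclass
class TruthInsertion:
    """A simulated L1 insertion with all generative parameters.

    ``junction5``/``junction3`` are 1-based reference coordinates, both
    inside the duplicated interval, so tsd_length == |j5 - j3| + 1.
    """

    chrom: str
    junction5: int
    junction3: int
    strand: str
    element_length: int
    inversion_length: int
    polya_length: int
    tsd_length: int
    somatic: bool = False
    blood_only_loss: bool = False
    sample_id: str = ""
    gene: str = "."
    cn: str = "NT"
    loh: str = "NT"
    partially_specified: bool = False
    haplotype: str = "B"  # A | B | both

    def validate(self, consensus_length: int) -> None:
        if self.tsd_length != abs(self.junction5 - self.junction3) + 1:
            raise InvariantError("tsd_length != |junction5 - junction3| + 1")
        if not (0 <= self.inversion_length < self.element_length):
            raise InvariantError("0 <= inversion_length < element_length violated")
        if self.element_length > consensus_length:
            raise InvariantError("element_length exceeds consensus length")
        if self.strand not in "+-":
            raise InvariantError("strand must be + or -")
        if min(self.junction5, self.junction3) < 1:
            raise InvariantError("junction coordinates must be positive")

    @property
    def site_start(self) -> int:
        return min(self.junction5, self.junction3)

    @property
    def site_end(self) -> int:
        return max(self.junction5, self.junction3)

    @property
    def inserted_length(self) -> int:
        return self.element_length + self.polya_length + self.tsd_length


@dataclass(frozen=True)
class L1Copy:
    """An annotated fixed (reference) L1 interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def three_prime_pos(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class ReferenceGenome:
    chromosomes: Haplotype
    fixed_l1: List[L1Copy] = field(default_factory=list)

    def copy_chromosomes(self) -> Haplotype:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class CnLohSegment:
    """A tumor copy-number / LOH segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    copy_number: int
    loh: bool

    def __post_init__(self):
        if self.start > self.end:
            raise InvariantError("segment start > end")
        if self.copy_number not in (1, 2):
            raise InvariantError("copy_number must be 1 or 2")
        if self.copy_number == 1 and not self.loh:
            raise InvariantError("copy_number 1 implies loh")

    def overlaps(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def validate_segments(segments: Sequence[CnLohSegment]) -> None:
    """Segments must be non-overlapping per sample."""
    by_chrom: Dict[str, List[CnLohSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise InvariantError(f"overlapping segments on {chrom}")


@dataclass
class PatientPair:
    """Matched blood/tumor genomes for one patient, with the truth ledger."""

    patient_id: str
    reference: ReferenceGenome
    blood: Tuple[Haplotype, Haplotype]
    tumor: Tuple[Haplotype, Haplotype]
    truth: List[TruthInsertion]
    segments: List[CnLohSegment] = field(default_factory=list)
    genes: List["_annotate.GeneModel"] = field(default_factory=list)
    off_target_sites: List[Tuple[str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference construction


def _random_chromosome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def build_reference(
    seed: int,
    chrom_lengths: Dict[str, int],
    n_fixed_l1: int,
    consensus: Optional[L1Consensus] = None,
    exclude: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    buffer: int = 2000,
    max_retries: int = 500,
) -> ReferenceGenome:
    """Random multi-chromosome reference with full-length fixed L1 copies.

    Copies (element + residual polyA) are written over the random sequence
    at uniformly drawn positions on random strands, keeping coordinates
    stable. ``exclude`` intervals (1-based inclusive, per chromosome) are
    kept free of copies — callers reserve future implant loci this way.
    """
    if any(l <= 0 for l in chrom_lengths.values()):
        raise InvariantError("chromosome lengths must be positive")
    if n_fixed_l1 < 0:
        raise InvariantError("n_fixed_l1 must be >= 0")
    cons = consensus or default_consensus()
    rng = substream(seed, "reference")
    chroms = {name: _random_chromosome(rng, length) for name, length in chrom_lengths.items()}
    copy_len = len(cons) + FIXED_L1_POLYA
    names = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    placed: List[L1Copy] = []
    exclude = exclude or {}
    for _ in range(n_fixed_l1):
        for attempt in range(max_retries):
            name = names[int(rng.choice(len(names), p=weights))]
            limit = chrom_lengths[name] - copy_len - buffer
            if limit <= buffer:
                continue
            start0 = int(rng.integers(buffer, limit))  # 0-based
            lo, hi = start0 + 1, start0 + copy_len  # 1-based inclusive
            clash = any(
                c.chrom == name and not (hi + buffer < c.start or lo - buffer > c.end)
                for c in placed
            ) or any(
                not (hi + buffer < s or lo - buffer > e)
                for s, e in exclude.get(name, [])
            )
            if clash:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            body = cons.sequence + "A" * FIXED_L1_POLYA
            if strand == "-":
                body = revcomp(body)
            seq = chroms[name]
            chroms[name] = seq[:start0] + body + seq[start0 + copy_len :]
            placed.append(L1Copy(chrom=name, start=lo, end=hi, strand=strand))
            break
        else:
            raise PlacementError(
                "could not place fixed L1 copy without overlap after "
                f"{max_retries} retries (constraint: no overlap with other copies "
                "or excluded intervals)"
            )
    placed.sort(key=lambda c: (c.chrom, c.start))
    return ReferenceGenome(chromosomes=chroms, fixed_l1=placed)


# ---------------------------------------------------------------------------
# implantation


def build_element(consensus: L1Consensus, element_length: int, inversion_length: int) -> str:
    """Element body in element orientation: inverted 5' segment + 3' portion."""
    seq = consensus.sequence
    start = len(seq) - element_length
    inv = revcomp(seq[start : start + inversion_length])
    return inv + seq[start + inversion_length :]


def build_allele(spec: TruthInsertion, consensus: L1Consensus) -> str:
    """Inserted bases (element [+polyA], genome orientation) without the TSD copy."""
    element = build_element(consensus, spec.element_length, spec.inversion_length)
    body = element + "A" * spec.polya_length
    return body if spec.strand == "+" else revcomp(body)


def implant_insertion(
    chroms: Haplotype,
    spec: TruthInsertion,
    consensus: Optional[L1Consensus] = None,
    fixed_l1: Sequence[L1Copy] = (),
    other_sites: Sequence[Tuple[int, int]] = (),
    validate_site: bool = True,
) -> Haplotype:
    """Insert one L1 allele, returning a new haplotype dict.

    The duplicated target site S = chrom[site_start..site_end] stays in
    place and a second copy is appended after the inserted body:
    ... S  body  S ... — so the chromosome grows by
    element_length + polya_length + tsd_length.

    With ``validate_site`` the realized locus is re-parsed by
    :func:`tipcall.annotate.characterize_insertion`; if the canonical parse
    differs from the requested parameters (boundary-ambiguous site) a
    :class:`SiteIncompatibleError` is raised so the caller can pick another
    position.
    """
    cons = consensus or default_consensus()
    spec.validate(len(cons))
    if spec.chrom not in chroms:
        raise InvariantError(f"unknown chromosome {spec.chrom}")
    seq = chroms[spec.chrom]
    lo, hi = spec.site_start, spec.site_end
    if hi > len(seq):
        raise InvariantError("target site outside chromosome bounds")
    for c in fixed_l1:
        if c.chrom == spec.chrom and not (hi < c.start or lo > c.end):
            raise InvariantError("target site intersects fixed L1 annotation")
    for s, e in other_sites:
        if not (hi < s or lo > e):
            raise InvariantError("target site intersects another implant")
    body = build_allele(spec, cons)
    site = seq[lo - 1 : hi]
    new_seq = seq[:hi] + body + site + seq[hi:]
    if validate_site:
        w = spec.tsd_length + 80
        flank5 = seq[max(0, hi - w) : hi]
        flank3 = seq[hi : hi + w]
        filled = flank5 + body + site + flank3
        try:
            parse = _annotate.characterize_insertion(filled, flank5, flank3, cons)
        except Exception as exc:  # noqa: BLE001 - reported as incompatibility
            raise SiteIncompatibleError(f"implanted allele does not parse: {exc}") from exc
        got = (
            parse.strand,
            parse.element_length,
            parse.inversion_length,
            parse.polya_length,
            parse.tsd_length,
        )
        want = (
            spec.strand,
            spec.element_length,
            spec.inversion_length,
            spec.polya_length,
            spec.tsd_length,
        )
        if got != want:
            raise SiteIncompatibleError(
                f"target site is boundary-ambiguous: canonical parse {got} != requested {want}"
            )
    out = dict(chroms)
    out[spec.chrom] = new_seq
    return out


def implant_insertions(
    chroms: Haplotype,
    specs: Sequence[TruthInsertion],
    consensus: Optional[L1Consensus] = None,
    fixed_l1: Sequence[L1Copy] = (),
    validate_site: bool = True,
) -> Haplotype:
    """Apply several implants, high coordinates first, so positions stay valid."""
    out = dict(chroms)
    done: Dict[str, List[Tuple[int, int]]] = {}
    for spec in sorted(specs, key=lambda s: (s.chrom, -s.site_end)):
        out = implant_insertion(
            out,
            spec,
            consensus,
            fixed_l1=fixed_l1,
            other_sites=done.get(spec.chrom, []),
            validate_site=validate_site,
        )
        done.setdefault(spec.chrom, []).append((spec.site_start, spec.site_end))
    return out


def build_sample_haplotypes(
    reference: ReferenceGenome,
    insertions: Sequence[TruthInsertion],
    consensus: Optional[L1Consensus] = None,
    validate_site: bool = True,
) -> Tuple[Haplotype, Haplotype]:
    """Diploid sample: haplotype A (plus 'both'/'A' implants) and B (carrier)."""
    on_a = [i for i in insertions if i.haplotype in ("A", "both")]
    on_b = [i for i in insertions if i.haplotype in ("B", "both")]
    hap_a = implant_insertions(
        reference.copy_chromosomes(), on_a, consensus, reference.fixed_l1, validate_site
    )
    hap_b = implant_insertions(
        reference.copy_chromosomes(), on_b, consensus, reference.fixed_l1, validate_site
    )
    return hap_a, hap_b


def apply_cn_loh(
    pair: PatientPair,
    segments: Sequence[CnLohSegment],
    consensus: Optional[L1Consensus] = None,
) -> PatientPair:
    """Apply tumor CN/LOH segments, rebuilding the tumor haplotypes.

    A germline heterozygous insertion whose target site falls inside a
    segment loses its carrier haplotype in the tumor: under a deletion
    (CN 1) the carrier copy is gone; under copy-neutral LOH (CN 2) it is
    replaced by the insertion-free homolog. Either way the tumor carries
    no insertion there and the truth ledger marks it blood-only.
    """
    validate_segments(segments)
    truth = [replace(t) for t in pair.truth]
    for t in truth:
        seg = next(
            (s for s in segments if s.overlaps(t.chrom, t.site_start)), None
        )
        if seg is None:
            continue
        if t.haplotype == "both":
            raise InvariantError(
                "CN/LOH segment overlaps a homozygous insertion; cannot remove both copies"
            )
        if not t.somatic:
            t.blood_only_loss = True
            t.cn = str(seg.copy_number)
            t.loh = "Y" if seg.loh else "N"
    tumor_insertions = [
        t for t in truth if t.somatic or not t.blood_only_loss
    ]
    tumor = build_sample_haplotypes(pair.reference, tumor_insertions, consensus)
    return PatientPair(
        patient_id=pair.patient_id,
        reference=pair.reference,
        blood=pair.blood,
        tumor=tumor,
        truth=truth,
        segments=list(segments),
        genes=pair.genes,
        off_target_sites=pair.off_target_sites,
    )
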