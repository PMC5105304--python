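"""Preset cohort: ten matched tumor/blood pairs with known insertions.

The presets reproduce a published-style validated-insertion table on
synthetic 400-kb chromosomes: eleven blood-specific germline insertions
(each lost from the tumor through a deletion or copy-neutral LOH segment)
across six patients, one tumor-specific somatic insertion with a 5'
inversion in a seventh, and three insertion-free patients. Printed
genomic coordinates are mapped onto the synthetic chromosomes by
``((coord - 1) mod chrom_length) + 1``, which preserves every junction
pair's offset and therefore every TSD length.

Rows whose 5' junction was never sequenced ("partial" insertions) are
realized with default element/TSD parameters and flagged
``partially_specified`` so reports print them with placeholders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .annotate import GeneModel
from .consensus import L1Consensus, default_consensus
from .errors import PlacementError, SiteIncompatibleError
from .genome import (
    CnLohSegment,
    PatientPair,
    ReferenceGenome,
    TruthInsertion,
    apply_cn_loh,
    build_reference,
    build_sample_haplotypes,
    implant_insertion,
)
from .rng import child_seed, substream

__all__ = [
    "PresetRow",
    "PRINTED_ROWS",
    "PATIENTS",
    "table2_presets",
    "build_table2_cohort",
]


@dataclass(frozen=True)
class PresetRow:
    """One row of the validated-insertion table, in printed coordinates."""

    sample_id: str
    chrom: str
    junction5: Optional[int]  # None when the 5' junction was not sequenced
    junction3: int
    strand: str
    element_length: Optional[int]
    inversion_length: int
    tsd_length: Optional[int]
    gene: str
    cn: str
    loh: str
    somatic: bool = False


PRINTED_ROWS: Tuple[PresetRow, ...] = (
    # blood-specific (germline, lost from the tumor genome)
    PresetRow("750", "chr5", None, 34495746, "+", None, 0, None, ".", "1", "Y"),
    PresetRow("750", "chr13", 50488000, 50487984, "+", 4162, 0, 17, "GUCY1B2", "1", "Y"),
    PresetRow("772", "chr14", 33209876, 33209888, "-", 5422, 0, 13, "NPAS3", "1", "Y"),
    PresetRow("832", "chr10", 31557469, 31557476, "-", 6059, 0, 8, ".", "1", "Y"),
    PresetRow("847", "chr11", 33626714, 33626699, "+", 1281, 0, 16, "KIAA1549L", "1", "Y"),
    PresetRow("847", "chr11", None, 94317493, "-", None, 0, None, ".", "1", "Y"),
    PresetRow("897", "chr8", 24982467, 24982461, "-", 2845, 0, 7, ".", "2", "Y"),
    PresetRow("897", "chr8", 119790870, 119790884, "-", 965, 0, 15, "SAMD12AS1", "2", "Y"),
    PresetRow("897", "chr13", 85238154, 85238150, "-", 684, 0, 5, ".", "1", "Y"),
    PresetRow("897", "chr14", None, 30220577, "-", None, 0, None, "SCFD1", "2", "Y"),
    PresetRow("922", "chr11", 33626714, 33626699, "+", 1281, 0, 16, "KIAA1549L", "1", "Y"),
    # tumor-specific (somatic, with a twin-priming 5' inversion)
    PresetRow("083", "chr17", 47881841, 47881832, "+", 1839, 662, 10, ".", "NT", "NT", True),
)

# cohort order: discovery patients first, then the extension set
PATIENTS: Tuple[str, ...] = (
    "714", "750", "772", "832", "847", "897", "922", "007", "023", "083",
)


def _map_coord(coord: int, chrom_length: int) -> int:
    return ((coord - 1) % chrom_length) + 1


def table2_presets(
    chrom_length: int = 400_000,
    default_element_length: int = 3000,
    default_tsd: int = 12,
    polya_length: int = 30,
) -> List[TruthInsertion]:
    """The preset rows as concrete, implantable truth insertions."""
    out: List[TruthInsertion] = []
    for row in PRINTED_ROWS:
        j3 = _map_coord(row.junction3, chrom_length)
        partial = row.junction5 is None
        if partial:
            j5 = j3 + default_tsd - 1
            element, tsd = default_element_length, default_tsd
        else:
            j5 = _map_coord(row.junction5, chrom_length)
            element, tsd = row.element_length, row.tsd_length
        out.append(
            TruthInsertion(
                chrom=row.chrom,
                junction5=j5,
                junction3=j3,
                strand=row.strand,
                element_length=element,
                inversion_length=row.inversion_length,
                polya_length=polya_length,
                tsd_length=tsd,
                somatic=row.somatic,
                sample_id=row.sample_id,
                gene=row.gene,
                cn=row.cn,
                loh=row.loh,
                partially_specified=partial,
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort factory


_BASES = "ACGT"


def _rotate_base(seq: str, pos: int) -> str:
    """Deterministically replace the base at ``pos`` (0-based) with the next one."""
    cur = seq[pos]
    new = _BASES[(_BASES.index(cur) + 1) % 4] if cur in _BASES else "C"
    return seq[:pos] + new + seq[pos + 1 :]


def _harden_site(
    reference: ReferenceGenome,
    spec: TruthInsertion,
    consensus: L1Consensus,
    max_attempts: int = 96,
) -> None:
    """Mutate reference bases near the locus until the implant parses cleanly.

    An implant can land in sequence whose bases extend its TSD, polyA tail,
    or element (a one-off shifted parse), in which case the canonical
    re-parse disagrees with the requested parameters. The offending base
    can sit just outside the duplicated interval or inside it, so single
    bases are rotated in a fixed cycle spiralling outward from the site
    boundaries on both flanks and through the interval interior. The locus
    never moves; the mutation is applied to the patient reference so every
    haplotype inherits it.
    """
    lo0 = spec.site_start - 1  # 0-based first base of the duplicated interval
    hi0 = spec.site_end - 1  # 0-based last base of the duplicated interval
    cycle = [lo0 - 1, hi0 + 1, hi0, lo0, lo0 - 2, hi0 + 2, hi0 - 1, lo0 + 1]
    for attempt in range(max_attempts):
        try:
            implant_insertion(
                reference.chromosomes, spec, consensus, reference.fixed_l1
            )
            return
        except SiteIncompatibleError:
            pos = cycle[attempt % len(cycle)]
            seq = reference.chromosomes[spec.chrom]
            if not 0 <= pos < len(seq):
                continue
            reference.chromosomes[spec.chrom] = _rotate_base(seq, pos)
    raise PlacementError(
        f"could not realize an unambiguous insertion site at "
        f"{spec.chrom}:{spec.site_start}-{spec.site_end} after {max_attempts} attempts"
    )


def _merge_segments(segments: Sequence[CnLohSegment]) -> List[CnLohSegment]:
    """Merge overlapping segments with identical CN/LOH state."""
    merged: List[CnLohSegment] = []
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if (
            merged
            and merged[-1].chrom == s.chrom
            and s.start <= merged[-1].end + 1
            and merged[-1].copy_number == s.copy_number
            and merged[-1].loh == s.loh
        ):
            prev = merged.pop()
            merged.append(replace(prev, end=max(prev.end, s.end)))
        else:
            merged.append(s)
    return merged


def _gene_models(
    truth: Sequence[TruthInsertion], chrom_length: int
) -> List[GeneModel]:
    genes: Dict[str, GeneModel] = {}
    for t in truth:
        if t.gene == "." or t.gene in genes:
            continue
        start = max(1, t.site_start - 8000)
        end = min(chrom_length, t.site_end + 12000)
        # terminal exons only, so the insertion itself is intronic
        exons = ((start, start + 199), (end - 199, end))
        genes[t.gene] = GeneModel(
            name=t.gene, chrom=t.chrom, start=start, end=end, strand="+", exons=exons
        )
    return list(genes.values())


def _off_target_sites(
    seed: int,
    patient_id: str,
    chrom_lengths: Dict[str, int],
    reference: ReferenceGenome,
    truth: Sequence[TruthInsertion],
    n_sites: int = 8,
    clearance: int = 18_000,
    max_retries: int = 2000,
) -> List[Tuple[str, int, str]]:
    """Nonspecific amplification sites, kept far from every known element."""
    rng = substream(seed, "offtarget", patient_id)
    names = sorted(chrom_lengths)
    keep_away: Dict[str, List[Tuple[int, int]]] = {}
    for c in reference.fixed_l1:
        keep_away.setdefault(c.chrom, []).append((c.start, c.end))
    for t in truth:
        keep_away.setdefault(t.chrom, []).append((t.site_start, t.site_end))
    sites: List[Tuple[str, int, str]] = []
    for _ in range(n_sites):
        for _attempt in range(max_retries):
            name = names[int(rng.integers(0, len(names)))]
            length = chrom_lengths[name]
            pos = int(rng.integers(5000, max(5001, length - 5000)))
            near = any(
                pos >= s - clearance and pos <= e + clearance
                for s, e in keep_away.get(name, [])
            ) or any(
                c == name and abs(p - pos) < 4000 for c, p, _ in sites
            )
            if near:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append((name, pos, strand))
            break
        else:
            raise PlacementError(
                f"could not place {n_sites} off-target sites with {clearance} bp "
                "clearance from annotated elements"
            )
    return sites


def build_table2_cohort(
    seed: int,
    chrom_length: int = 400_000,
    n_fixed_l1: int = 6,
    n_off_target: int = 8,
    segment_flank: int = 25_000,
    consensus: Optional[L1Consensus] = None,
    default_element_length: int = 3000,
    default_tsd: int = 12,
    polya_length: int = 30,
) -> Dict[str, PatientPair]:
    """Build the ten matched patient genomes for the preset insertion table.

    Each patient gets a private random reference (one 400-kb chromosome per
    implant chromosome; insertion-free patients get a single ``chr1``),
    ``n_fixed_l1`` annotated full-length fixed copies, blood haplotypes
    carrying the germline insertions heterozygously, tumor CN/LOH segments
    spanning every germline locus (so each is blood-specific), and the
    somatic insertion in the tumor only.
    """
    cons = consensus or default_consensus()
    presets = table2_presets(
        chrom_length=chrom_length,
        default_element_length=default_element_length,
        default_tsd=default_tsd,
        polya_length=polya_length,
    )
    cohort: Dict[str, PatientPair] = {}
    for pid in PATIENTS:
        truth = [replace(t) for t in presets if t.sample_id == pid]
        chrom_names = sorted({t.chrom for t in truth}) or ["chr1"]
        lengths = {name: chrom_length for name in chrom_names}
        exclude = {}
        for t in truth:
            exclude.setdefault(t.chrom, []).append(
                (max(1, t.site_start - 12_000), min(chrom_length, t.site_end + 12_000))
            )
        reference = build_reference(
            child_seed(seed, "ref", pid), lengths, n_fixed_l1, cons, exclude=exclude
        )
        for t in truth:
            _harden_site(reference, t, cons)
        germline = [t for t in truth if not t.somatic]
        blood = build_sample_haplotypes(reference, germline, cons)
        tumor = build_sample_haplotypes(reference, truth, cons)
        segments = _merge_segments(
            CnLohSegment(
                chrom=t.chrom,
                start=max(1, t.site_start - segment_flank),
                end=min(chrom_length, t.site_end + segment_flank),
                copy_number=int(t.cn),
                loh=t.loh == "Y",
            )
            for t in germline
        )
        genes = _gene_models(truth, chrom_length)
        pair = PatientPair(
            patient_id=pid,
            reference=reference,
            blood=blood,
            tumor=tumor,
            truth=truth,
            genes=genes,
            off_target_sites=_off_target_sites(
                seed, pid, lengths, reference, truth, n_sites=n_off_target
            ),
        )
        pair = apply_cn_loh(pair, segments, cons)
        cohort[pid] = pair
    return cohort
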