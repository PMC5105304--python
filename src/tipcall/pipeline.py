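"""End-to-end pipeline: simulate, align, call, score, compare, validate, report.

One patient pair flows through:

1. simulate vectorette reads from each haplotype of blood and tumor;
2. align to the patient reference with annotated L1 copies masked;
3. call pileup peaks and recover polyA junction reads;
4. compute five features per peak, train the within-sample logistic
   scorer on annotated fixed copies (positives) vs junction-less distal
   peaks (presumed negatives), and score every candidate;
5. build junction consensus sequences and classify each candidate as
   insertion-supported or not;
6. compare tumor vs blood call sets both directions, validate each
   discordant call by in-silico spanning amplification, and annotate
   normal-only calls with the covering tumor CN/LOH segment;
7. characterize each validated insertion (strand, element length,
   inversion, polyA, TSD) by parsing the carrier haplotype's filled
   allele against the empty reference site, and render the report table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .align import GenomeIndex, align_reads, mask_reference
from .annotate import (
    AnnotatedInsertion,
    characterize_insertion,
    gene_overlap,
    render_report,
)
from .consensus import L1Consensus, default_consensus
from .errors import FormatError, InvariantError, NotL1InsertionError
from .genome import Haplotype, PatientPair
from .peaks import (
    build_consensus,
    call_peaks,
    classify_consensus,
    extract_junction_reads,
)
from .presets import build_table2_cohort
from .rng import child_seed
from .scoring import (
    CandidateCall,
    Scorer,
    _distance,
    peak_feature_table,
    score_candidates,
    select_candidates,
    train_model,
)
from .simulate import DEFAULT_ENZYMES, ReadSet, simulate_vectorette_reads
from .somatic import (
    DiscordantCall,
    compare_call_sets,
    insilico_validate,
    integrate_cn_loh,
    _pick_primer,
    _find_unique,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SampleResult",
    "PatientResult",
    "CohortResult",
    "run_sample",
    "run_patient_pair",
    "run_cohort",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; loadable from YAML."""

    seed: int = 1
    chrom_length: int = 400_000
    n_fixed_l1: int = 6
    n_off_target: int = 8
    coverage: float = 30.0
    error_rate: float = 0.002
    layout: str = "single"
    enzymes: Tuple[str, ...] = DEFAULT_ENZYMES
    background_fraction: float = 0.05
    min_peak_reads: int = 3
    max_peak_gap: int = 100
    junction_end_len: int = 35
    min_polyat: int = 6
    junction_cap: int = 200
    junction_window: int = 500
    compare_window: int = 200
    primer_flank: int = 20
    max_amplicon: int = 10_000
    min_insert: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise FormatError(f"{path}: unknown config keys: {', '.join(unknown)}")
        if "enzymes" in raw:
            raw["enzymes"] = tuple(raw["enzymes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["enzymes"] = list(data["enzymes"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SampleResult:
    sample_id: str
    calls: List[CandidateCall]  # novel, insertion-supported calls
    candidates: List[CandidateCall]  # everything scored
    scorer: Optional[Scorer]
    n_reads: int
    n_peaks: int


@dataclass
class PatientResult:
    patient_id: str
    blood: SampleResult
    tumor: SampleResult
    tumor_only: List[DiscordantCall]
    normal_only: List[DiscordantCall]
    shared: int
    annotated: List[AnnotatedInsertion]


@dataclass
class CohortResult:
    results: Dict[str, PatientResult]
    report: pd.DataFrame
    summary: Dict[str, int]


# ---------------------------------------------------------------------------
# per-sample analysis


def run_sample(
    haplotypes: Sequence[Haplotype],
    pair: PatientPair,
    index: GenomeIndex,
    masked: Haplotype,
    config: PipelineConfig,
    sample_label: str,
    consensus: Optional[L1Consensus] = None,
) -> SampleResult:
    """Simulate, align, peak-call, score, and classify one sample."""
    cons = consensus or default_consensus()
    sample_id = f"{pair.patient_id}.{sample_label}"
    reads: List = []
    layout = config.layout
    for h, hap in enumerate(haplotypes):
        rs, _ = simulate_vectorette_reads(
            hap,
            enzymes=config.enzymes,
            coverage=config.coverage,
            error_rate=config.error_rate,
            seed=child_seed(config.seed, "sim", pair.patient_id, sample_label, h),
            layout=layout,
            consensus=cons,
            background_fraction=config.background_fraction,
            off_target_sites=pair.off_target_sites,
            sample_id=f"{sample_id}.hap{h}",
        )
        reads.extend(rs.reads)
    readset = ReadSet(reads=reads, sample_id=sample_id, layout=layout)

    alignments = align_reads(readset, index)
    peaks = call_peaks(alignments, min_reads=config.min_peak_reads, max_gap=config.max_peak_gap)

    seq_by_id: Dict[str, str] = {}
    for r in reads:
        if r.mate_sequence is None:
            seq_by_id[r.id] = r.sequence
        else:
            seq_by_id[r.id + "/1"] = r.sequence
            seq_by_id[r.id + "/2"] = r.mate_sequence
    unmapped = [
        (a.read_id, seq_by_id[a.read_id]) for a in alignments if a.status == "unmapped"
    ]
    junction_map = extract_junction_reads(
        unmapped,
        index,
        peaks,
        end_len=config.junction_end_len,
        min_polyat=config.min_polyat,
        cap=config.junction_cap,
        window=config.junction_window,
    )

    candidates = select_candidates(peaks, junction_map, layout=layout, sample_id=sample_id)
    peak_features = peak_feature_table(peaks, alignments, junction_map)
    for c in candidates:
        c.features = peak_features[c.peak]

    junction_peaks = {c.peak for c in candidates}
    negative_pool = {p: fv for p, fv in peak_features.items() if p not in junction_peaks}
    scorer: Optional[Scorer] = None
    try:
        scorer = train_model(
            candidates,
            pair.reference.fixed_l1,
            peak_features=negative_pool,
            seed=child_seed(config.seed, "train", pair.patient_id, sample_label),
        )
        candidates = score_candidates(scorer, candidates)
    except InvariantError as exc:
        log.warning("%s: scorer not trained (%s); calls proceed unscored", sample_id, exc)

    template = cons.three_prime_template()
    calls: List[CandidateCall] = []
    for c in candidates:
        c.consensus = build_consensus(c.junction_reads)
        c.verdict = classify_consensus(c.consensus, masked, template)
        if (
            c.verdict.verdict == "insertion_supported"
            and _distance(c.peak, pair.reference.fixed_l1) > 1000
        ):
            calls.append(c)
    calls.sort(key=lambda c: (c.peak.chrom, c.boundary))
    return SampleResult(
        sample_id=sample_id,
        calls=calls,
        candidates=candidates,
        scorer=scorer,
        n_reads=len(reads),
        n_peaks=len(peaks),
    )


# ---------------------------------------------------------------------------
# characterization of validated loci


def _characterize_locus(
    call: CandidateCall,
    carrier_haps: Sequence[Haplotype],
    reference: Haplotype,
    consensus: L1Consensus,
    anchor_len: int = 30,
    offsets: Tuple[int, int] = (300, 650),
    min_insert: int = 50,
):
    """Parse the filled allele at a validated locus against the empty site.

    Unique anchors flanking the locus are located in the reference and in
    each carrier haplotype; the haplotype whose inter-anchor segment is
    longer than the reference's carries the insertion, and that filled
    allele is characterized base-by-base. Returns
    (InsertionParse, ref_tsd_start, ref_tsd_end) or None.
    """
    chrom = call.peak.chrom
    left = _pick_primer(reference, chrom, call.boundary, -1, anchor_len, offsets)
    right = _pick_primer(reference, chrom, call.boundary, +1, anchor_len, offsets)
    if left is None or right is None:
        return None
    lstart, lseq = left
    rstart, rseq = right
    empty = reference[chrom][lstart : rstart + anchor_len]
    filled = None
    for hap in carrier_haps:
        lhit = _find_unique(hap, lseq)
        rhit = _find_unique(hap, rseq)
        if lhit is None or rhit is None or lhit[0] != rhit[0]:
            continue
        segment = hap[lhit[0]][lhit[1] : rhit[1] + anchor_len]
        if len(segment) >= len(empty) + min_insert and (
            filled is None or len(segment) > len(filled)
        ):
            filled = segment
    if filled is None:
        return None
    mid = len(empty) // 2
    try:
        parse = characterize_insertion(filled, empty[:mid], empty[mid:], consensus)
    except NotL1InsertionError:
        return None
    # empty-site position q (1-based) sits at reference coordinate lstart + q
    return parse, lstart + parse.tsd_start, lstart + parse.tsd_end


def _annotate_discordant(
    d: DiscordantCall,
    pair: PatientPair,
    consensus: L1Consensus,
) -> AnnotatedInsertion:
    call = d.candidate
    carrier = pair.tumor if d.direction == "tumor_only" else pair.blood
    parsed = _characterize_locus(call, carrier, pair.reference.chromosomes, consensus)
    chrom = call.peak.chrom
    if parsed is None:
        ctx = gene_overlap(chrom, call.boundary, pair.genes)
        return AnnotatedInsertion(
            sample_id=pair.patient_id,
            chrom=chrom,
            junction5=call.boundary,
            junction3=call.boundary,
            strand=".",
            element_length=None,
            inversion_length=None,
            polya_length=None,
            tsd_length=None,
            gene=ctx.gene if ctx.feature != "intergenic" else ".",
            feature=ctx.feature,
            cn=d.cn,
            loh=d.loh,
            somatic=d.direction == "tumor_only",
            partially_specified=True,
        )
    parse, tsd_lo, tsd_hi = parsed
    if parse.strand == "+":
        j5, j3 = tsd_hi, tsd_lo
    else:
        j5, j3 = tsd_lo, tsd_hi
    ctx = gene_overlap(chrom, tsd_lo, pair.genes)
    return AnnotatedInsertion(
        sample_id=pair.patient_id,
        chrom=chrom,
        junction5=j5,
        junction3=j3,
        strand=parse.strand,
        element_length=parse.element_length,
        inversion_length=parse.inversion_length,
        polya_length=parse.polya_length,
        tsd_length=parse.tsd_length,
        gene=ctx.gene if ctx.feature != "intergenic" else ".",
        feature=ctx.feature,
        cn=d.cn,
        loh=d.loh,
        somatic=d.direction == "tumor_only",
    )


# ---------------------------------------------------------------------------
# patient and cohort drivers


def run_patient_pair(
    pair: PatientPair,
    config: PipelineConfig,
    consensus: Optional[L1Consensus] = None,
) -> PatientResult:
    cons = consensus or default_consensus()
    masked = mask_reference(pair.reference.chromosomes, pair.reference.fixed_l1)
    index = GenomeIndex(masked)
    blood = run_sample(pair.blood, pair, index, masked, config, "blood", cons)
    tumor = run_sample(pair.tumor, pair, index, masked, config, "tumor", cons)

    tumor_only_calls, normal_only_calls, shared = compare_call_sets(
        tumor.calls, blood.calls, window=config.compare_window
    )

    def validate(calls: List[CandidateCall], direction: str) -> List[DiscordantCall]:
        out = []
        for c in calls:
            res = insilico_validate(
                c,
                pair.blood,
                pair.tumor,
                pair.reference.chromosomes,
                direction=direction,
                primer_flank=config.primer_flank,
                max_amplicon=config.max_amplicon,
                min_insert=config.min_insert,
            )
            out.append(
                DiscordantCall(
                    direction=direction,
                    candidate=c,
                    validation=res.verdict,
                    result=res,
                )
            )
        return out

    tumor_only = validate(tumor_only_calls, "tumor_only")
    normal_only = validate(normal_only_calls, "normal_only")
    integrate_cn_loh(normal_only, pair.segments)

    annotated = [
        _annotate_discordant(d, pair, cons)
        for d in tumor_only + normal_only
        if d.validation == "productive"
    ]
    return PatientResult(
        patient_id=pair.patient_id,
        blood=blood,
        tumor=tumor,
        tumor_only=tumor_only,
        normal_only=normal_only,
        shared=len(shared) // 2,
        annotated=annotated,
    )


def run_cohort(
    config: PipelineConfig,
    cohort: Optional[Dict[str, PatientPair]] = None,
    consensus: Optional[L1Consensus] = None,
) -> CohortResult:
    cons = consensus or default_consensus()
    if cohort is None:
        cohort = build_table2_cohort(
            config.seed,
            chrom_length=config.chrom_length,
            n_fixed_l1=config.n_fixed_l1,
            n_off_target=config.n_off_target,
            consensus=cons,
        )
    results: Dict[str, PatientResult] = {}
    annotated: List[AnnotatedInsertion] = []
    for pid, pair in cohort.items():
        log.info("analyzing patient %s", pid)
        res = run_patient_pair(pair, config, cons)
        results[pid] = res
        annotated.extend(res.annotated)
    report = render_report(annotated)
    summary = {
        "patients": len(results),
        "validated_normal_only": sum(
            1
            for r in results.values()
            for d in r.normal_only
            if d.validation == "productive"
        ),
        "validated_tumor_only": sum(
            1
            for r in results.values()
            for d in r.tumor_only
            if d.validation == "productive"
        ),
        "discordant_normal_only": sum(len(r.normal_only) for r in results.values()),
        "discordant_tumor_only": sum(len(r.tumor_only) for r in results.values()),
        "shared_calls": sum(r.shared for r in results.values()),
    }
    return CohortResult(results=results, report=report, summary=summary)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> CohortResult:
    """Full cohort run writing report, summary, truth ledger, and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = build_table2_cohort(
        config.seed,
        chrom_length=config.chrom_length,
        n_fixed_l1=config.n_fixed_l1,
        n_off_target=config.n_off_target,
    )
    result = run_cohort(config, cohort=cohort)

    from .io import write_truth_tsv

    config.to_yaml(out / "config.yaml")
    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    truth = [t for pair in cohort.values() for t in pair.truth]
    write_truth_tsv(out / "truth.tsv", truth)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2) + "\n")
    names = ["config.yaml", "report.tsv", "truth.tsv", "summary.json"]
    manifest = "".join(f"{_sha256(out / n)}  {n}\n" for n in names)
    (out / "manifest.sha256").write_text(manifest)
    return result
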