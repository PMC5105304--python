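"""File-backed pipeline stages.

Each stage reads the previous stage's artifacts from the run directory and
writes its own, so every subcommand can be rerun in isolation. Layout::

    <run>/config.yaml
    <run>/<patient>/reference.fa     l1.bed  genes.gff  segments.tsv
    <run>/<patient>/truth.tsv        blood.hap0.fa ... tumor.hap1.fa
    <run>/<patient>/<sample>.fastq                         (simulate)
    <run>/<patient>/<sample>.aln.tsv                       (align)
    <run>/<patient>/<sample>.peaks.tsv  .junctions.tsv     (call)
    <run>/<patient>/<sample>.candidates.tsv  .model.txt  .calls.tsv  (score)
    <run>/<patient>/discordant.tsv                         (compare)
    <run>/report.tsv  summary.json  manifest.sha256        (annotate)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from types import SimpleNamespace
from typing import Dict, List, Optional, Tuple

from .align import GenomeIndex, ReadAlignment, align_reads, mask_reference
from .annotate import render_report
from .consensus import default_consensus
from .errors import FormatError, InvariantError
from .genome import L1Copy, PatientPair
from .io import (
    read_bed,
    read_fasta,
    read_fastq,
    read_gff,
    read_segments_tsv,
    read_truth_tsv,
    write_alignments_tsv,
    read_alignments_tsv,
    write_bed,
    write_fasta,
    write_fastq,
    write_gff,
    write_segments_tsv,
    write_truth_tsv,
)
from .peaks import (
    JunctionRead,
    Peak,
    _orient,
    build_consensus,
    call_peaks,
    classify_consensus,
    extract_junction_reads,
    longest_at_run,
)
from .pipeline import PipelineConfig, _annotate_discordant, _sha256
from .presets import build_table2_cohort
from .rng import child_seed
from .scoring import (
    _distance,
    peak_feature_table,
    score_candidates,
    select_candidates,
    train_model,
)
from .simulate import ReadSet, simulate_vectorette_reads
from .somatic import DiscordantCall, ValidationResult, compare_call_sets, insilico_validate, integrate_cn_loh

log = logging.getLogger(__name__)

SAMPLES = ("blood", "tumor")

__all__ = [
    "stage_simulate",
    "stage_align",
    "stage_call",
    "stage_score",
    "stage_compare",
    "stage_annotate",
    "run_all_stages",
]


def _patients(run_dir: Path) -> List[Path]:
    pats = sorted(
        p for p in run_dir.iterdir() if p.is_dir() and (p / "reference.fa").exists()
    )
    if not pats:
        raise FormatError(f"{run_dir}: no simulated patients found; run 'simulate' first")
    return pats


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FormatError(f"{path} missing; run '{stage}' first")
    return path


def _tsv_rows(path: Path, header: List[str]) -> List[Dict[str, str]]:
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != header:
        raise FormatError(f"{path} line 1: expected header {header}")
    rows = []
    for n, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path} line {n}: expected {len(header)} columns")
        rows.append(dict(zip(header, parts)))
    return rows


def _write_tsv(path: Path, header: List[str], rows: List[List]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# stage: simulate


def stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    cons = default_consensus()
    cohort = build_table2_cohort(
        config.seed,
        chrom_length=config.chrom_length,
        n_fixed_l1=config.n_fixed_l1,
        n_off_target=config.n_off_target,
        consensus=cons,
    )
    for pid, pair in cohort.items():
        pdir = run_dir / pid
        pdir.mkdir(exist_ok=True)
        write_fasta(pdir / "reference.fa", pair.reference.chromosomes)
        write_bed(pdir / "l1.bed", pair.reference.fixed_l1)
        write_gff(pdir / "genes.gff", pair.genes)
        write_segments_tsv(pdir / "segments.tsv", pair.segments)
        write_truth_tsv(pdir / "truth.tsv", pair.truth)
        _write_tsv(
            pdir / "offtarget.tsv",
            ["chrom", "pos0", "strand"],
            [[c, p, s] for c, p, s in pair.off_target_sites],
        )
        for label, haps in (("blood", pair.blood), ("tumor", pair.tumor)):
            reads = []
            for h, hap in enumerate(haps):
                write_fasta(pdir / f"{label}.hap{h}.fa", hap)
                rs, _ = simulate_vectorette_reads(
                    hap,
                    enzymes=config.enzymes,
                    coverage=config.coverage,
                    error_rate=config.error_rate,
                    seed=child_seed(config.seed, "sim", pid, label, h),
                    layout=config.layout,
                    consensus=cons,
                    background_fraction=config.background_fraction,
                    off_target_sites=pair.off_target_sites,
                    sample_id=f"{pid}.{label}.hap{h}",
                )
                reads.extend(rs.reads)
            write_fastq(
                pdir / f"{label}.fastq",
                ReadSet(reads=reads, sample_id=f"{pid}.{label}", layout=config.layout),
            )
        log.info("simulate: patient %s written (%d truth insertions)", pid, len(pair.truth))


# ---------------------------------------------------------------------------
# shared loaders


def _load_index(pdir: Path) -> Tuple[GenomeIndex, Dict[str, str], List[L1Copy]]:
    ref = read_fasta(_require(pdir / "reference.fa", "simulate"))
    copies = [
        L1Copy(chrom=c, start=s, end=e, strand=strand)
        for c, s, e, _name, strand in read_bed(_require(pdir / "l1.bed", "simulate"))
    ]
    masked = mask_reference(ref, copies)
    return GenomeIndex(masked), masked, copies


def _load_reads(pdir: Path, sample: str) -> List[Tuple[str, str]]:
    return [
        (rid, seq)
        for rid, seq, _q in read_fastq(_require(pdir / f"{sample}.fastq", "simulate"))
    ]


# ---------------------------------------------------------------------------
# stage: align


def stage_align(config: PipelineConfig, run_dir: Path) -> None:
    for pdir in _patients(Path(run_dir)):
        index, _masked, _copies = _load_index(pdir)
        for sample in SAMPLES:
            reads = _load_reads(pdir, sample)
            alignments = align_reads(reads, index)
            write_alignments_tsv(pdir / f"{sample}.aln.tsv", alignments)
            n_unique = sum(1 for a in alignments if a.status == "unique")
            log.info(
                "align: %s/%s %d reads, %d unique",
                pdir.name, sample, len(alignments), n_unique,
            )


# ---------------------------------------------------------------------------
# stage: call (peaks + junction reads)

_PEAK_COLS = ["chrom", "start", "end", "read_count", "max_coverage", "rank"]
_JUNCTION_COLS = [
    "peak_rank", "read_id", "anchored_end", "overhang",
    "anchor_chrom", "anchor_start", "anchor_end", "anchor_strand", "anchor_mismatches",
]


def _write_peaks(path: Path, peaks: List[Peak]) -> None:
    _write_tsv(
        path,
        _PEAK_COLS,
        [[p.chrom, p.start, p.end, p.read_count, p.max_coverage, p.rank] for p in peaks],
    )


def _read_peaks(path: Path) -> List[Peak]:
    return [
        Peak(
            chrom=r["chrom"], start=int(r["start"]), end=int(r["end"]),
            read_count=int(r["read_count"]), max_coverage=int(r["max_coverage"]),
            rank=int(r["rank"]),
        )
        for r in _tsv_rows(path, _PEAK_COLS)
    ]


def _write_junctions(path: Path, junction_map: Dict[Peak, List[JunctionRead]]) -> None:
    rows = []
    for peak in sorted(junction_map, key=lambda p: p.rank):
        for j in junction_map[peak]:
            rows.append(
                [
                    peak.rank, j.read_id, j.anchored_end, j.overhang,
                    j.anchor.chrom, j.anchor.start, j.anchor.end,
                    j.anchor.strand, j.anchor.mismatches,
                ]
            )
    _write_tsv(path, _JUNCTION_COLS, rows)


def _read_junctions(path: Path, peaks: List[Peak]) -> Dict[Peak, List[JunctionRead]]:
    by_rank = {p.rank: p for p in peaks}
    out: Dict[Peak, List[JunctionRead]] = {p: [] for p in peaks}
    for n, r in enumerate(_tsv_rows(path, _JUNCTION_COLS), start=2):
        rank = int(r["peak_rank"])
        if rank not in by_rank:
            raise FormatError(f"{path} line {n}: unknown peak rank {rank}")
        anchor = ReadAlignment(
            read_id=r["read_id"], chrom=r["anchor_chrom"],
            start=int(r["anchor_start"]), end=int(r["anchor_end"]),
            strand=r["anchor_strand"], mismatches=int(r["anchor_mismatches"]),
            status="unique",
        )
        side, overhang_plus, boundary = _orient(r["anchored_end"], anchor, r["overhang"])
        out[by_rank[rank]].append(
            JunctionRead(
                read_id=r["read_id"], anchored_end=r["anchored_end"], anchor=anchor,
                overhang=r["overhang"], overhang_plus=overhang_plus, side=side,
                boundary=boundary, polyat_run=longest_at_run(r["overhang"]),
            )
        )
    return out


def stage_call(config: PipelineConfig, run_dir: Path) -> None:
    for pdir in _patients(Path(run_dir)):
        index, _masked, _copies = _load_index(pdir)
        for sample in SAMPLES:
            alignments = read_alignments_tsv(_require(pdir / f"{sample}.aln.tsv", "align"))
            peaks = call_peaks(
                alignments, min_reads=config.min_peak_reads, max_gap=config.max_peak_gap
            )
            seq_by_id = dict(_load_reads(pdir, sample))
            unmapped = [
                (a.read_id, seq_by_id[a.read_id])
                for a in alignments
                if a.status == "unmapped"
            ]
            junction_map = extract_junction_reads(
                unmapped, index, peaks,
                end_len=config.junction_end_len, min_polyat=config.min_polyat,
                cap=config.junction_cap, window=config.junction_window,
            )
            _write_peaks(pdir / f"{sample}.peaks.tsv", peaks)
            _write_junctions(pdir / f"{sample}.junctions.tsv", junction_map)
            log.info(
                "call: %s/%s %d peaks, %d junction reads",
                pdir.name, sample, len(peaks),
                sum(len(v) for v in junction_map.values()),
            )


# ---------------------------------------------------------------------------
# stage: score

_CAND_COLS = [
    "chrom", "peak_start", "peak_end", "boundary", "peak_width", "peak_depth",
    "variant_index", "polya_purity", "junction_read_count", "probability",
    "label", "verdict",
]
_CALL_COLS = ["chrom", "peak_start", "peak_end", "boundary", "probability", "verdict"]


def stage_score(config: PipelineConfig, run_dir: Path) -> None:
    cons = default_consensus()
    template = cons.three_prime_template()
    for pdir in _patients(Path(run_dir)):
        _index, masked, copies = _load_index(pdir)
        for sample in SAMPLES:
            alignments = read_alignments_tsv(_require(pdir / f"{sample}.aln.tsv", "align"))
            peaks = _read_peaks(_require(pdir / f"{sample}.peaks.tsv", "call"))
            junction_map = _read_junctions(
                _require(pdir / f"{sample}.junctions.tsv", "call"), peaks
            )
            candidates = select_candidates(
                peaks, junction_map, layout=config.layout,
                sample_id=f"{pdir.name}.{sample}",
            )
            peak_features = peak_feature_table(peaks, alignments, junction_map)
            for c in candidates:
                c.features = peak_features[c.peak]
            junction_peaks = {c.peak for c in candidates}
            negative_pool = {
                p: fv for p, fv in peak_features.items() if p not in junction_peaks
            }
            try:
                scorer = train_model(
                    candidates, copies, peak_features=negative_pool,
                    seed=child_seed(config.seed, "train", pdir.name, sample),
                )
                candidates = score_candidates(scorer, candidates)
                (pdir / f"{sample}.model.txt").write_text(scorer.export_text())
            except InvariantError as exc:
                log.warning("score: %s/%s scorer not trained (%s)", pdir.name, sample, exc)
            cand_rows, call_rows = [], []
            for c in candidates:
                c.consensus = build_consensus(c.junction_reads)
                c.verdict = classify_consensus(c.consensus, masked, template)
                prob = "." if c.probability is None else f"{c.probability:.6g}"
                fv = c.features
                cand_rows.append(
                    [
                        c.peak.chrom, c.peak.start, c.peak.end, c.boundary,
                        int(fv.peak_width), int(fv.peak_depth),
                        f"{fv.variant_index:.6g}", f"{fv.polya_purity:.6g}",
                        int(fv.junction_read_count), prob, c.label, c.verdict.verdict,
                    ]
                )
                if (
                    c.verdict.verdict == "insertion_supported"
                    and _distance(c.peak, copies) > 1000
                ):
                    call_rows.append(
                        [c.peak.chrom, c.peak.start, c.peak.end, c.boundary, prob,
                         c.verdict.verdict]
                    )
            call_rows.sort(key=lambda r: (r[0], int(r[3])))
            _write_tsv(pdir / f"{sample}.candidates.tsv", _CAND_COLS, cand_rows)
            _write_tsv(pdir / f"{sample}.calls.tsv", _CALL_COLS, call_rows)
            log.info(
                "score: %s/%s %d candidates, %d novel calls",
                pdir.name, sample, len(cand_rows), len(call_rows),
            )


# ---------------------------------------------------------------------------
# stage: compare (+ in-silico validation, CN/LOH)

_DISC_COLS = [
    "direction", "chrom", "peak_start", "peak_end", "boundary",
    "validation", "empty_size", "cn", "loh",
]


def _read_calls(path: Path) -> List[SimpleNamespace]:
    calls = []
    for r in _tsv_rows(path, _CALL_COLS):
        peak = SimpleNamespace(
            chrom=r["chrom"], start=int(r["peak_start"]), end=int(r["peak_end"])
        )
        calls.append(SimpleNamespace(peak=peak, boundary=int(r["boundary"])))
    return calls


def _load_haps(pdir: Path, label: str) -> Tuple[Dict[str, str], Dict[str, str]]:
    return (
        read_fasta(_require(pdir / f"{label}.hap0.fa", "simulate")),
        read_fasta(_require(pdir / f"{label}.hap1.fa", "simulate")),
    )


def stage_compare(config: PipelineConfig, run_dir: Path) -> None:
    for pdir in _patients(Path(run_dir)):
        reference = read_fasta(pdir / "reference.fa")
        blood_haps = _load_haps(pdir, "blood")
        tumor_haps = _load_haps(pdir, "tumor")
        segments = read_segments_tsv(_require(pdir / "segments.tsv", "simulate"))
        tumor_calls = _read_calls(_require(pdir / "tumor.calls.tsv", "score"))
        blood_calls = _read_calls(_require(pdir / "blood.calls.tsv", "score"))
        tumor_only, normal_only, _shared = compare_call_sets(
            tumor_calls, blood_calls, window=config.compare_window
        )
        rows = []
        discordant: List[DiscordantCall] = []
        for direction, calls in (("tumor_only", tumor_only), ("normal_only", normal_only)):
            for c in calls:
                res = insilico_validate(
                    c, blood_haps, tumor_haps, reference,
                    direction=direction, primer_flank=config.primer_flank,
                    max_amplicon=config.max_amplicon, min_insert=config.min_insert,
                )
                discordant.append(
                    DiscordantCall(
                        direction=direction, candidate=c,
                        validation=res.verdict, result=res,
                    )
                )
        integrate_cn_loh([d for d in discordant if d.direction == "normal_only"], segments)
        for d in discordant:
            c = d.candidate
            rows.append(
                [
                    d.direction, c.peak.chrom, c.peak.start, c.peak.end, c.boundary,
                    d.validation,
                    "." if d.result.empty_size is None else d.result.empty_size,
                    d.cn, d.loh,
                ]
            )
        rows.sort(key=lambda r: (r[0], r[1], int(r[4])))
        _write_tsv(pdir / "discordant.tsv", _DISC_COLS, rows)
        # shared list holds each concordant call once per sample
        (pdir / "compare.stats.json").write_text(
            json.dumps({"shared_calls": len(_shared) // 2}) + "\n"
        )
        log.info(
            "compare: %s %d tumor-only, %d normal-only discordant calls",
            pdir.name, len(tumor_only), len(normal_only),
        )


# ---------------------------------------------------------------------------
# stage: annotate (report + summary + manifest)


def stage_annotate(config: PipelineConfig, run_dir: Path) -> None:
    run_dir = Path(run_dir)
    cons = default_consensus()
    annotated = []
    summary = {
        "patients": 0,
        "validated_normal_only": 0,
        "validated_tumor_only": 0,
        "discordant_normal_only": 0,
        "discordant_tumor_only": 0,
        "shared_calls": 0,
    }
    for pdir in _patients(run_dir):
        summary["patients"] += 1
        stats = json.loads(_require(pdir / "compare.stats.json", "compare").read_text())
        summary["shared_calls"] += stats["shared_calls"]
        reference = read_fasta(pdir / "reference.fa")
        genes = read_gff(_require(pdir / "genes.gff", "simulate"))
        blood_haps = _load_haps(pdir, "blood")
        tumor_haps = _load_haps(pdir, "tumor")
        pair = SimpleNamespace(
            patient_id=pdir.name,
            reference=SimpleNamespace(chromosomes=reference),
            blood=blood_haps,
            tumor=tumor_haps,
            genes=genes,
        )
        for r in _tsv_rows(_require(pdir / "discordant.tsv", "compare"), _DISC_COLS):
            summary[f"discordant_{r['direction']}"] += 1
            if r["validation"] != "productive":
                continue
            summary[f"validated_{r['direction']}"] += 1
            peak = SimpleNamespace(
                chrom=r["chrom"], start=int(r["peak_start"]), end=int(r["peak_end"])
            )
            call = SimpleNamespace(peak=peak, boundary=int(r["boundary"]))
            d = DiscordantCall(
                direction=r["direction"], candidate=call,
                validation=r["validation"], cn=r["cn"], loh=r["loh"],
            )
            annotated.append(_annotate_discordant(d, pair, cons))
    report = render_report(annotated)
    report.to_csv(run_dir / "report.tsv", sep="\t", index=False)
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    artifacts = sorted(
        p for p in run_dir.rglob("*")
        if p.is_file() and p.name != "manifest.sha256"
    )
    manifest = "".join(
        f"{_sha256(p)}  {p.relative_to(run_dir)}\n" for p in artifacts
    )
    (run_dir / "manifest.sha256").write_text(manifest)
    log.info(
        "annotate: %d validated insertions (%d blood-only, %d tumor-only)",
        len(annotated), summary["validated_normal_only"], summary["validated_tumor_only"],
    )


STAGES = (
    ("simulate", stage_simulate),
    ("align", stage_align),
    ("call", stage_call),
    ("score", stage_score),
    ("compare", stage_compare),
    ("annotate", stage_annotate),
)


def run_all_stages(config: PipelineConfig, run_dir: Path) -> None:
    for name, fn in STAGES:
        log.info("=== stage %s ===", name)
        try:
            fn(config, run_dir)
        except Exception:
            log.error("stage %s failed; partial outputs retained in %s", name, run_dir)
            raise
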