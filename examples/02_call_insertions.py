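"""From reads to scored candidate insertion sites, step by step, one sample.

The read-level analysis has two complementary routes that meet at the end:
peaks of uniquely mapped reads rank loci by amplification evidence, and
unmappable reads whose terminal 35 bp anchors uniquely next to a peak with
a polyA-bearing overhang provide junction evidence. Peaks with junction
evidence become candidates, described by five features and scored with a
within-sample logistic model trained on the annotated fixed L1 copies.
"""

from tipcall import PipelineConfig
from tipcall.align import GenomeIndex, align_reads, mask_reference
from tipcall.peaks import call_peaks, extract_junction_reads
from tipcall.presets import build_table2_cohort
from tipcall.rng import child_seed
from tipcall.scoring import peak_feature_table, score_candidates, select_candidates, train_model
from tipcall.simulate import simulate_vectorette_reads

config = PipelineConfig()
pair = build_table2_cohort(config.seed)["897"]

# annotated L1 copies are masked so their internal sequence never maps
masked = mask_reference(pair.reference.chromosomes, pair.reference.fixed_l1)
index = GenomeIndex(masked)

reads = []
for h in (0, 1):
    rs, _ = simulate_vectorette_reads(
        pair.blood[h], coverage=config.coverage,
        seed=child_seed(config.seed, "sim", pair.patient_id, "blood", h),
        sample_id=f"897.blood.hap{h}", off_target_sites=pair.off_target_sites,
    )
    reads.extend(rs.reads)
print(f"{len(reads)} reads simulated")

alignments = align_reads([(r.id, r.sequence) for r in reads], index)
by_status = {}
for a in alignments:
    by_status[a.status] = by_status.get(a.status, 0) + 1
print(f"alignment: {by_status}")

peaks = call_peaks(alignments, min_reads=config.min_peak_reads, max_gap=config.max_peak_gap)
print(f"{len(peaks)} pileup peaks; top 3 by depth:")
for p in peaks[:3]:
    print(f"  rank {p.rank}: {p.chrom}:{p.start}-{p.end} depth={p.max_coverage} reads={p.read_count}")

seq_by_id = {r.id: r.sequence for r in reads}
unmapped = [(a.read_id, seq_by_id[a.read_id]) for a in alignments if a.status == "unmapped"]
junction_map = extract_junction_reads(unmapped, index, peaks)
n_junction = sum(len(v) for v in junction_map.values())
print(f"{n_junction} polyA junction reads recovered at {sum(1 for v in junction_map.values() if v)} peaks")

candidates = select_candidates(peaks, junction_map, sample_id="897.blood")
features = peak_feature_table(peaks, alignments, junction_map)
for c in candidates:
    c.features = features[c.peak]

negative_pool = {p: fv for p, fv in features.items() if p not in {c.peak for c in candidates}}
scorer = train_model(
    candidates, pair.reference.fixed_l1, peak_features=negative_pool,
    seed=child_seed(config.seed, "train", pair.patient_id, "blood"),
)
print(f"\nscorer trained on {scorer.n_positive} positives / {scorer.n_negative} negatives")
print(scorer.export_text())

scored = score_candidates(scorer, candidates)
print("candidates away from annotated copies (putative non-reference insertions):")
from tipcall.scoring import _distance

for c in scored:
    if _distance(c.peak, pair.reference.fixed_l1) > 1000:
        print(
            f"  {c.peak.chrom}:{c.boundary} p={c.probability:.3f} "
            f"junction_reads={len(c.junction_reads)}"
        )
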