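"""Build one preset patient and look at what the simulator produces.

A patient is a matched blood/tumor pair of diploid genomes derived from a
shared random reference carrying annotated full-length L1 copies. Germline
insertions live on one haplotype of both samples; tumor copy-number / LOH
segments can delete the carrier haplotype locally, which is what makes an
insertion blood-only. Vectorette reads are then simulated per haplotype.
"""

from tipcall import PipelineConfig
from tipcall.presets import build_table2_cohort
from tipcall.rng import child_seed
from tipcall.simulate import simulate_vectorette_reads

config = PipelineConfig()  # seed 1, 30x junction coverage, six enzymes
cohort = build_table2_cohort(config.seed)
pair = cohort["897"]

print(f"patient {pair.patient_id}")
print(f"  chromosomes: {sorted(pair.reference.chromosomes)}")
print(f"  fixed L1 copies: {len(pair.reference.fixed_l1)}")
print(f"  off-target amplification sites: {len(pair.off_target_sites)}")

print("\ntruth ledger (germline insertions on haplotype B):")
for t in pair.truth:
    kind = "somatic" if t.somatic else ("blood-only" if t.blood_only_loss else "germline")
    print(
        f"  {t.chrom}:{t.junction5}/{t.junction3} {t.strand} "
        f"element={t.element_length} tsd={t.tsd_length} {kind} cn={t.cn} loh={t.loh}"
    )

print("\ntumor CN/LOH segments:")
for s in pair.segments:
    print(f"  {s.chrom}:{s.start}-{s.end} cn={s.copy_number} loh={'Y' if s.loh else 'N'}")

reads, amplicons = simulate_vectorette_reads(
    pair.blood[1],  # the insertion-carrying blood haplotype
    coverage=config.coverage,
    seed=child_seed(config.seed, "sim", pair.patient_id, "blood", 1),
    sample_id="897.blood.hap1",
    off_target_sites=pair.off_target_sites,
)
l1_amps = [a for a in amplicons if a.kind == "l1"]
print(f"\nsimulated {len(reads)} reads from {len(amplicons)} amplicons "
      f"({len(l1_amps)} L1-anchored)")
print("each L1 3' end yields one amplicon per enzyme; lengths from one locus:")
first_chrom, first_start = l1_amps[0].chrom, l1_amps[0].start
for a in l1_amps:
    if (a.chrom, a.start) == (first_chrom, first_start) or abs(a.start - first_start) < 50:
        print(f"  {a.enzyme:8s} {a.chrom}:{a.start}-{a.end}  {len(a.sequence)} bp")
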