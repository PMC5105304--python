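# tipcall

Somatic LINE-1 insertion analysis for TIPseq (transposon insertion
profiling by sequencing), as a fully simulated, fully reproducible model
system: matched tumor/blood genome simulation with a truth ledger,
vectorette-PCR read simulation, insertion calling from pileup peaks and
polyA junction reads, a five-feature logistic candidate scorer,
bidirectional tumor-normal comparison with in-silico spanning-PCR
validation, tumor copy-number/LOH integration, and annotation of the
target-primed reverse transcription hallmarks (target-site duplication,
5' truncation, twin-priming 5' inversion, polyA tail) of every validated
insertion.

## The science in one paragraph

Active LINE-1 (L1) retrotransposons copy themselves into new genomic
locations through target-primed reverse transcription, leaving a
recognizable scar: a short target-site duplication (TSD) flanking the
element, an intact 3' end with a polyA tail, frequent 5' truncation, and
sometimes an inverted 5' segment from twin priming. TIPseq finds
non-reference insertions by vectorette PCR: a primer anchored in the L1
3'UTR amplifies through the polyA tail into unique flanking DNA, so
insertion loci show up as sharp pileups of flank-mapped reads plus
unmappable reads that cross the junction. Comparing a tumor with the
patient's blood classifies each insertion as shared (germline),
tumor-only (somatic), or — more often than naively expected — blood-only:
a germline insertion that *disappears* from the tumor because a deletion
or copy-neutral loss of heterozygosity removed the carrier haplotype.
Distinguishing these outcomes requires validation and copy-number
context, which this package models end to end against a known ground
truth.

## Quick start

Library, one patient end to end (this is `examples/03_tumor_normal_comparison.py`;
output shown verbatim):

```python
from tipcall import PipelineConfig
from tipcall.pipeline import run_patient_pair
from tipcall.presets import build_table2_cohort

config = PipelineConfig()                       # master seed 1
pair = build_table2_cohort(config.seed)["897"]  # one preset patient
result = run_patient_pair(pair, config)
```

```text
patient 897
  blood: 14616 reads, 27 peaks, 4 novel insertion calls
  tumor: 10704 reads, 15 peaks, 0 novel insertion calls
  shared calls: 0

blood-only (normal-only) calls after validation:
  chr13:38127 -> productive (empty=440 blood=(440, 1159) tumor=(440,)) cn=1 loh=Y
  chr14:220560 -> productive (empty=440 blood=(440, 3482) tumor=(440,)) cn=2 loh=Y
  chr8:182457 -> productive (empty=440 blood=(440, 3322) tumor=(440,)) cn=2 loh=Y
  chr8:190854 -> productive (empty=440 blood=(440, 1450) tumor=(440,)) cn=2 loh=Y

tumor-only calls after validation:
  none

hallmarks of the validated insertions:
  chr13:38150/38154 - element=684 tsd=5 inversion=0 polyA=30 gene=. (intergenic)
  chr14:220577/220588 - element=3000 tsd=12 inversion=0 polyA=30 gene=SCFD1 (intron)
  chr8:182461/182467 - element=2845 tsd=7 inversion=0 polyA=30 gene=. (intergenic)
  chr8:190870/190884 - element=965 tsd=15 inversion=0 polyA=30 gene=SAMD12AS1 (intron)
```

All four of patient 897's germline insertions are blood-only: the
in-silico spanning PCR shows the filled-site product in blood but only
the empty-site product in the tumor, and each locus sits inside a tumor
LOH segment (cn=1 is a deletion, cn=2 copy-neutral LOH) — tumor-side loss
of the carrier haplotype, not blood-side retrotransposition. The
recovered hallmarks (element length, TSD, polyA, gene context) match the
truth ledger exactly.

CLI — the same pipeline through ledgered file-backed stages:

```bash
tipcall run-all -o runs/demo                 # full cohort, default config
tipcall simulate -o runs/demo --seed 2       # or stage by stage:
tipcall align    -o runs/demo --seed 2       # simulate, align, call,
tipcall call     -o runs/demo --seed 2       # score, compare, annotate
...
```

Flags override the YAML config (`--config cfg.yaml --seed 9` uses the
file's values except the seed). Each run directory ends up with
`report.tsv`, `truth.tsv`, `summary.json`, per-patient intermediates
(FASTA/FASTQ/BED/GFF3/TSV), and `manifest.sha256` over every artifact;
rerunning with the same configuration reproduces the manifest byte for
byte.

More walkthroughs in `examples/`:

- `01_simulate_patient.py` — genomes, truth ledger, amplicon structure
- `02_call_insertions.py` — alignment, peaks, junction reads, scoring
- `03_tumor_normal_comparison.py` — comparison, validation, hallmarks
- `04_full_cohort_replay.py` — the ten-patient cohort with artifacts

`docs/methods.md` describes every algorithm in detail.

## The preset cohort

`tipcall.presets.build_table2_cohort` constructs ten patients. Nine of
the twelve implanted insertions are fully specified (element lengths 684
to 6,059 bp, TSDs 5 to 17 bp), three are partially specified germline
events, and one is a somatic insertion with a 662 bp twin-priming
inversion inside an 1,839 bp element. Eleven insertions are germline and
lost from the tumor through CN/LOH segments (blood-only); three patients
are insertion-free controls. Replaying the cohort at the default seed
recovers all twelve:

```text
summary: {'patients': 10, 'validated_normal_only': 11, 'validated_tumor_only': 1,
          'discordant_normal_only': 11, 'discordant_tumor_only': 1, 'shared_calls': 0}
```

## Reproduction

```bash
# acceptance target: validated blood-only insertion count (expected 11)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# -> {"t8": {"value": 11, "n": 11}}

# full test suite, including the acceptance tests
python -m pytest tests/
```

The acceptance tests (`tests/test_acceptance.py`) pin: the TSD arithmetic
on every fully specified preset junction pair; the preset element-length
extremes; the full-replay counts (11 blood-only, 1 tumor-only, all
blood-only with LOH); zero validated discordant calls across 20
insertion-free seeds; exact agreement of the aligner, peak ranking,
candidate counting and gene-context code with brute-force oracles; and
exact parser recovery of 200 randomized error-free implants.

## Repository layout

```
src/tipcall/      library (simulation, alignment, calling, scoring,
                  comparison, annotation, pipeline, CLI)
examples/         narrative walkthroughs
docs/methods.md   algorithm descriptions
scripts/          acceptance entry point
tests/            pytest suite with brute-force oracles
```
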