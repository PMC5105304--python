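# Methods

`tipcall` is a self-contained model system for calling somatic and
blood-only LINE-1 (L1) insertions from transposon insertion profiling by
sequencing (TIPseq) data. It couples a generative simulator of matched
tumor/blood genomes and vectorette-PCR sequencing with an analysis
pipeline that recovers non-reference insertions, compares the two samples
of each patient, validates discordant calls in silico, and annotates the
target-primed reverse transcription (TPRT) hallmarks of every validated
event. Every stochastic step derives from one master seed, so a run is
reproducible end to end.

Coordinates are 1-based inclusive everywhere in memory; BED output is the
only 0-based half-open representation, converted at the file boundary.

## 1. Synthetic genomes and the truth ledger

Each patient has a private random reference (uniform ACGT) of one or more
chromosomes. Full-length copies of a 6,059 bp L1 consensus (plus a 20 bp
residual polyA) are written over the reference at random positions and
strands, with 2 kb buffers, and recorded as the annotated fixed-L1 set.
Zones reserved for later implants are excluded.

An insertion is specified by chromosome, the two junction coordinates, a
strand, element length (3' portion of the consensus), optional 5'
inversion length, polyA length, and target-site duplication (TSD) length.
The two junctions both lie inside the duplicated interval, so
`tsd = |junction5 - junction3| + 1`. Implantation duplicates the target
site S and inserts `element(+inversion) + polyA` between the copies:
`... S body S ...`, growing the chromosome by
`element + polyA + tsd` bases. On the minus strand the body is
reverse-complemented. The realized locus is immediately re-parsed
(section 7); if the canonical parse differs from the requested parameters
the site is boundary-ambiguous and implantation fails with
`SiteIncompatibleError`, so genome construction retries at a perturbed
position. Every accepted implant is appended to the patient's truth
ledger.

Samples are diploid. Germline heterozygous insertions are implanted on
haplotype B of both blood and tumor. Tumor copy-number (CN) / loss of
heterozygosity (LOH) segments then rebuild the tumor: a germline
insertion whose site falls inside a segment loses its carrier haplotype —
by deletion (CN 1) or by replacement with the insertion-free homolog
(copy-neutral LOH, CN 2) — and is marked blood-only in the ledger.
Somatic insertions are implanted in the tumor only.

## 2. Vectorette sequencing simulator

The simulator emulates the assay. For every occurrence of the 30 bp
primer anchor in the L1 3'UTR (annotated copies and implanted elements
alike), and for each enzyme in the panel (AseI, BspHI, BstYI, HindIII,
NcoI, PstI), an amplicon runs from the anchor through the polyA tail into
flanking DNA up to the first downstream recognition site (capped at
4 kb). Each amplicon is sheared into 75–100 bp single-end reads (paired
layout optional) at `coverage / n_enzymes` depth with a per-base
substitution error rate (default 0.002). Because the six amplicons from
one junction share their junction-proximal end but stop at different
cut sites, per-base depth is maximal at the junction and decays in steps
downstream — the signature pileup shape the caller exploits.

Noise is modeled two ways: nonspecific "off-target" amplicons (800–2,500
bp, no L1 content) at preset genomic positions sampled at a fraction of
signal depth, and uniformly placed background reads (default 5% of the
library).

## 3. Alignment

Reads are aligned to the patient reference with all annotated fixed-L1
intervals masked to N, so element-internal sequence cannot map and each
L1-adjacent pileup reflects flank sequence only.

The mapper is an exhaustive-within-its-model ungapped seed-and-extend
aligner: a sorted exact 17-mer index over the masked genome; per read, a
mismatch allowance of `floor(3 * length / 100)`; seeds at k-spaced
offsets plus the final k-mer. With `allowance + 1` disjoint seed windows,
any placement within the allowance contains at least one error-free seed
(pigeonhole), so the mapper provably enumerates *all* qualifying
placements. A read is `unique` when exactly one placement attains the
best mismatch count and the runner-up (among qualifying placements) is at
least 2 mismatches worse; otherwise `multi`; no qualifying placement
means `unmapped`. This contract is a pure function of genome and read and
is tested against a brute-force sliding-window oracle.

## 4. Peaks and junction reads

Uniquely mapped reads are piled per chromosome; maximal covered runs are
merged across gaps of at most 100 bp, runs with fewer than 3 overlapping
reads are dropped, and the surviving peaks are ranked by maximum
per-base depth (ties break by coordinate).

Reads the genome mapper rejects are re-examined for junction evidence:
the first and last 35 bp of each unmapped read are aligned independently.
A read qualifies as a junction read when exactly one end maps uniquely
and the unaligned overhang carries a mononucleotide A or T run of at
least 6 bp — the polyA tail crossing from flank into element. The
overhang is re-expressed on the reference plus strand, assigned a
genomic side (left/right of the anchor) and a junction boundary
coordinate, grouped to the nearest peak within 500 bp, and capped at 200
reads per peak.

Per candidate, junction overhangs are justified at the median boundary
and majority-voted column by column into a consensus (support ≥ 2 reads,
stray boundaries > 50 bp off are dropped). The consensus is then split at
the boundary: bases that extend the reference are stripped, and the
remaining core is compared against the element 3'-end + polyA template
with a local aligner (identity ≥ 0.85), with a fast path for ≥ 80% pure
A/T cores. The verdict is `insertion_supported`, `reference_only`, or
`ambiguous`.

## 5. Candidate scoring

Every peak with at least one junction read (one junction-containing
fragment, in paired layout) is a candidate, described by five features:

1. peak width (bp),
2. peak depth (maximum per-base coverage),
3. variant index (mean per-read mismatch fraction inside the peak),
4. polyA purity of the junction-outward overhangs,
5. junction read count.

The scorer is trained within each sample: candidates whose peak lies
within 500 bp of an annotated fixed-L1 3' end are known positives;
junction-less peaks farther than 10 kb from any annotated element (the
off-target amplicon peaks) are presumed negatives. Features are
standardized and fit with an L2-regularized logistic regression; each
candidate receives a probability. Calls are not thresholded on the
probability — downstream validation is the gate — but the probability
ranks candidates and is reported. A candidate is a *novel* call when its
consensus verdict is `insertion_supported` and its peak lies more than
1 kb from every annotated copy.

## 6. Comparison, in-silico validation, CN/LOH integration

The tumor and blood call sets of a patient are compared symmetrically: a
call is shared when the other sample has a call on the same chromosome
with a junction boundary within 200 bp; the rest are tumor-only or
normal-only (blood-only).

Each discordant call is validated by an in-silico analog of spanning PCR.
Unique exact-match 20-mers are searched 200–450 bp upstream and
downstream of the boundary in the patient reference; if either side has
no genome-wide-unique primer the call is `untested`. Product sizes are
computed on all four haplotypes (two per sample). The validation is
`productive` when the filled-site product (empty-site size + ≥ 50 bp)
appears in the call's own sample and not in the other; otherwise
`unproductive`.

Validated normal-only calls are intersected with the tumor CN/LOH
segment table; the covering segment's copy number and LOH flag are
attached (`NT` when uncovered), showing whether tumor-side loss of the
carrier haplotype explains the blood-only observation.

## 7. Hallmark characterization

Validated loci are characterized from assembled alleles rather than read
fragments: unique 30-mer anchors are placed 300–650 bp on both sides of
the boundary; the inter-anchor segment is extracted from the reference
(empty allele) and from each carrier haplotype, and a haplotype segment
at least 50 bp longer than the reference is the filled allele.

`characterize_insertion` recovers the TPRT hallmarks by enumerating every
indel placement of the insert between the common prefix and suffix of the
filled and empty alleles. For each placement the TSD is the longest exact
duplication (≤ 60 bp) between the insert's 3' end and the adjacent
upstream sequence; the polyA tail is the terminal mononucleotide run in
element orientation (≥ 5 bp); the remainder must match the consensus 3'
end exactly, allowing a reverse-complemented 5' segment whose sequence
equals the reverse complement of the consensus segment immediately 5' of
the non-inverted part (twin-priming inversion geometry). Among valid
parses the canonical one maximizes (element length, polyA length, TSD
length). Because implantation rejects boundary-ambiguous sites against
this same parser, the parse of any implanted locus reproduces the
generating parameters exactly; chance duplications that would defeat the
greedy TSD cannot occur at accepted sites.

Junction coordinates are reported from the TSD interval with the
convention junction5 = max(end) on plus-strand insertions and min(start)
on minus-strand insertions. Each insertion is placed in gene context
(exon > intron > intergenic-with-distance) against the patient's gene
models. The report table separates blood-specific and tumor-specific
sections and carries CN/LOH for blood-specific rows.

## 8. Determinism and artifacts

All randomness flows from a single master seed through named substreams
(`SeedSequence` children keyed by strings such as
`("sim", patient, sample, haplotype)`), so adding or reordering one step
does not perturb another. `run_pipeline` writes `config.yaml`,
`report.tsv`, `truth.tsv`, `summary.json` and a `manifest.sha256`; the
file-backed CLI stages (`simulate`, `align`, `call`, `score`, `compare`,
`annotate`, or `run-all`) additionally persist every intermediate
(FASTA/FASTQ/BED/GFF3/TSV) per patient and produce the same summary.
Rerunning with the same configuration reproduces the manifests byte for
byte.
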