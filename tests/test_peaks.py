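"""Peak calling (vs a pileup oracle), junction recovery, consensus, classification."""

import numpy as np
import pytest

from tipcall.align import GenomeIndex, ReadAlignment
from tipcall.consensus import revcomp
from tipcall.errors import InvariantError
from tipcall.peaks import (
    JunctionRead,
    Peak,
    build_consensus,
    call_peaks,
    classify_consensus,
    extract_junction_reads,
    longest_at_run,
)

from conftest import random_seq


def oracle_peaks(alignments, min_reads=3, max_gap=100):
    """Independent per-base pileup oracle for peak calling and ranking."""
    by_chrom = {}
    for a in alignments:
        if a.status == "unique":
            by_chrom.setdefault(a.chrom, []).append(a)
    raw = []
    for chrom in sorted(by_chrom):
        alns = by_chrom[chrom]
        hi = max(a.end for a in alns)
        cov = np.zeros(hi + 2, dtype=int)
        for a in alns:
            cov[a.start : a.end + 1] += 1
        covered = sorted(np.flatnonzero(cov > 0).tolist())
        runs = []
        for p in covered:
            # uncovered gap between runs is p - prev_end - 1 bases
            if runs and p - runs[-1][1] - 1 <= max_gap:
                runs[-1][1] = p
            else:
                runs.append([p, p])
        for s, e in runs:
            n = sum(1 for a in alns if a.start <= e and a.end >= s)
            if n < min_reads:
                continue
            raw.append((chrom, s, e, n, int(cov[s : e + 1].max())))
    raw.sort(key=lambda r: (-r[4], r[0], r[1]))
    return raw


def _aln(rid, chrom, start, end, status="unique", mm=0):
    if status == "unmapped":
        return ReadAlignment(rid, None, None, None, None, None, status)
    return ReadAlignment(rid, chrom, start, end, "+", mm, status)


class TestCallPeaks:
    def test_matches_pileup_oracle(self, rng):
        for trial in range(20):
            alns = []
            for i in range(int(rng.integers(20, 120))):
                chrom = "cA" if rng.random() < 0.6 else "cB"
                # clustered starts produce realistic multi-peak pileups
                center = int(rng.integers(1, 10)) * 9000
                start = center + int(rng.integers(0, 800))
                end = start + int(rng.integers(40, 100))
                status = "unique" if rng.random() < 0.85 else "multi"
                alns.append(_aln(f"t{trial}r{i}", chrom, start, end, status))
            got = call_peaks(alns, min_reads=2, max_gap=50)
            want = oracle_peaks(alns, min_reads=2, max_gap=50)
            assert [
                (p.chrom, p.start, p.end, p.read_count, p.max_coverage) for p in got
            ] == want
            assert [p.rank for p in got] == list(range(1, len(got) + 1))

    def test_min_reads_filters(self):
        alns = [_aln("a", "c", 100, 180), _aln("b", "c", 120, 200)]
        assert call_peaks(alns, min_reads=3) == []
        assert len(call_peaks(alns, min_reads=2)) == 1

    def test_gap_merging(self):
        near = [_aln(f"n{i}", "c", 100, 180) for i in range(3)]
        far = [_aln(f"f{i}", "c", 240, 320) for i in range(3)]
        merged = call_peaks(near + far, min_reads=3, max_gap=100)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (100, 320)
        split = call_peaks(near + far, min_reads=3, max_gap=10)
        assert len(split) == 2

    def test_ranking_by_depth(self):
        deep = [_aln(f"d{i}", "c", 1000, 1080) for i in range(5)]
        shallow = [_aln(f"s{i}", "c", 50_000, 50_080) for i in range(3)]
        peaks = call_peaks(deep + shallow, min_reads=2)
        assert peaks[0].start == 1000 and peaks[0].rank == 1
        assert peaks[1].start == 50_000 and peaks[1].rank == 2


class TestLongestAtRun:
    def test_basic(self):
        assert longest_at_run("GGAAAATTTTTC") == 5
        assert longest_at_run("CGCG") == 0
        assert longest_at_run("AAAA") == 4
        assert longest_at_run("") == 0


@pytest.fixture(scope="module")
def genome(rng_module=None):
    rng = np.random.default_rng(99)
    return {"c": random_seq(rng, 40_000)}


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome)


class TestExtractJunctionReads:
    def test_polya_junction_recovered(self, genome, index):
        g = genome["c"]
        read = g[10_000:10_035] + "A" * 45  # anchor maps 10001-10035 (+)
        peak = Peak("c", 9_700, 10_030, 10, 10, rank=1)
        out = extract_junction_reads([("j1", read)], index, [peak])
        assert len(out[peak]) == 1
        jr = out[peak][0]
        assert jr.anchored_end == "five_prime"
        assert jr.side == "right" and jr.boundary == 10_035
        assert jr.polyat_run == 45
        assert jr.overhang_outward == "A" * 45

    def test_reverse_strand_orientation(self, genome, index):
        g = genome["c"]
        # read whose 5' 35 bp is the reverse complement of the + strand
        read = revcomp(g[10_000:10_035]) + "T" * 45
        peak = Peak("c", 10_030, 10_400, 10, 10, rank=1)
        out = extract_junction_reads([("j2", read)], index, [peak])
        jr = out[peak][0]
        assert jr.anchored_end == "five_prime" and jr.anchor.strand == "-"
        assert jr.side == "left" and jr.boundary == 10_001
        # + strand bases of a T-overhang read back as polyA outward
        assert jr.overhang_outward == "T" * 45

    def test_fully_genomic_read_rejected(self, genome, index):
        read = genome["c"][5_000:5_080]
        peak = Peak("c", 4_900, 5_100, 10, 10, rank=1)
        out = extract_junction_reads([("g1", read)], index, [peak])
        assert out[peak] == []

    def test_short_at_run_rejected(self, genome, index):
        g = genome["c"]
        rng = np.random.default_rng(3)
        read = g[10_000:10_035] + "AAAG" + random_seq(rng, 41)
        peak = Peak("c", 9_700, 10_030, 10, 10, rank=1)
        out = extract_junction_reads([("s1", read)], index, [peak], min_polyat=6)
        assert out[peak] == []

    def test_cap_and_window(self, genome, index):
        g = genome["c"]
        reads = [(f"c{i}", g[10_000 - i : 10_035 - i] + "A" * 45) for i in range(5)]
        peak = Peak("c", 9_700, 10_030, 10, 10, rank=1)
        capped = extract_junction_reads(reads, index, [peak], cap=2)
        assert len(capped[peak]) == 2
        far_peak = Peak("c", 30_000, 30_200, 10, 10, rank=1)
        out = extract_junction_reads(reads, index, [far_peak], window=500)
        assert out[far_peak] == []


def _jr(rid, chrom, boundary, side, overhang_plus, strand="+"):
    if side == "right":
        anchor = ReadAlignment(rid, chrom, boundary - 34, boundary, strand, 0, "unique")
    else:
        anchor = ReadAlignment(rid, chrom, boundary, boundary + 34, strand, 0, "unique")
    return JunctionRead(
        read_id=rid, anchored_end="five_prime", anchor=anchor,
        overhang=overhang_plus, overhang_plus=overhang_plus, side=side,
        boundary=boundary, polyat_run=longest_at_run(overhang_plus),
    )


class TestBuildConsensus:
    def test_right_side_majority(self):
        reads = [
            _jr("a", "c", 500, "right", "AAAAAACGTG"),
            _jr("b", "c", 500, "right", "AAAAAACGTT"),
            _jr("d", "c", 500, "right", "AAAAAACGTG"),
        ]
        res = build_consensus(reads)
        assert res.side == "right" and res.boundary == 500
        assert res.sequence == "AAAAAACGTG"
        assert res.outward == "AAAAAACGTG"

    def test_left_side_plus_strand_orientation(self):
        # bases on the + strand immediately left of the boundary
        s = "GCGTTTTTT"  # ends at coord boundary-1
        reads = [_jr("a", "c", 800, "left", s), _jr("b", "c", 800, "left", s)]
        res = build_consensus(reads)
        assert res.side == "left" and res.boundary == 800
        assert res.sequence == s
        assert res.outward == revcomp(s)

    def test_boundary_median_and_stray_filter(self):
        reads = [
            _jr("a", "c", 500, "right", "AAAAAAAA"),
            _jr("b", "c", 501, "right", "AAAAAAAA"),
            _jr("d", "c", 2_000, "right", "CCCCCCCC"),  # stray, dropped
        ]
        res = build_consensus(reads)
        assert res.boundary in (500, 501)
        assert set(res.sequence) == {"A"}

    def test_single_read(self):
        res = build_consensus([_jr("a", "c", 100, "right", "AAAAAAC")])
        assert res.sequence == "AAAAAAC" and res.n_reads == 1

    def test_empty_rejected(self):
        with pytest.raises(InvariantError):
            build_consensus([])


class TestClassifyConsensus:
    def _res(self, seq, side, boundary):
        from tipcall.peaks import ConsensusResult

        return ConsensusResult(sequence=seq, side=side, boundary=boundary, chrom="c", n_reads=3)

    def test_reference_only(self, genome, consensus):
        g = genome["c"]
        res = self._res(g[600:640], "right", 600)  # pure reference extension
        v = classify_consensus(res, genome, consensus.three_prime_template())
        assert v.verdict == "reference_only"

    def test_polya_supported(self, genome, consensus):
        res = self._res("A" * 40, "right", 600)
        v = classify_consensus(res, genome, consensus.three_prime_template())
        assert v.verdict == "insertion_supported" and v.orientation == "+"

    def test_polyt_left_supported(self, genome, consensus):
        res = self._res("T" * 40, "left", 600)
        v = classify_consensus(res, genome, consensus.three_prime_template())
        assert v.verdict == "insertion_supported" and v.orientation == "-"

    def test_element_fragment_supported(self, genome, consensus):
        core = consensus.sequence[-120:-60]
        res = self._res(core, "right", 600)
        v = classify_consensus(res, genome, consensus.three_prime_template())
        assert v.verdict == "insertion_supported"

    def test_random_core_ambiguous(self, genome, consensus, rng):
        res = self._res(random_seq(rng, 40), "right", 600)
        v = classify_consensus(res, genome, consensus.three_prime_template())
        assert v.verdict == "ambiguous"

    def test_genomic_strip_before_element(self, genome, consensus):
        g = genome["c"]
        seq = g[600:615] + "A" * 30  # 15 ref bases then a tail
        res = self._res(seq, "right", 600)
        v = classify_consensus(res, genome, consensus.three_prime_template())
        # the strip may eat tail bases when the reference continues in A
        extra = len(g[615:645]) - len(g[615:645].lstrip("A"))
        assert v.verdict == "insertion_supported"
        assert 15 <= v.genomic_bases <= 15 + extra
        assert v.genomic_bases + v.core_length == len(seq)
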