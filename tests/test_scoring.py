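"""Candidate selection, feature computation, and the logistic scorer."""

import numpy as np
import pytest

from tipcall.align import ReadAlignment
from tipcall.errors import InvariantError
from tipcall.genome import L1Copy
from tipcall.peaks import JunctionRead, Peak, longest_at_run
from tipcall.scoring import (
    FeatureVector,
    compute_features,
    polya_purity,
    score_candidates,
    select_candidates,
    train_model,
)


def _aln(rid, chrom, start, end, mm=0):
    return ReadAlignment(rid, chrom, start, end, "+", mm, "unique")


def _jr(rid, chrom, boundary, overhang="AAAAAAAAAA"):
    anchor = ReadAlignment(rid, chrom, boundary - 34, boundary, "+", 0, "unique")
    return JunctionRead(
        read_id=rid, anchored_end="five_prime", anchor=anchor,
        overhang=overhang, overhang_plus=overhang, side="right",
        boundary=boundary, polyat_run=longest_at_run(overhang),
    )


class TestPolyaPurity:
    def test_pure_tail(self):
        assert polya_purity("A" * 20) == 1.0

    def test_mixed_prefix(self):
        # 9 A's then one G: the longest dominated prefix is still >= 0.8 A
        assert polya_purity("AAAAAAAAAG") == 0.9

    def test_no_tail(self):
        assert polya_purity("GCGCGCGCGC") == 0.0

    def test_t_tail_counts(self):
        assert polya_purity("T" * 12) == 1.0


class TestFeatureVector:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(InvariantError):
            FeatureVector(-1, 1, 0, 0.5, 1)
        with pytest.raises(InvariantError):
            FeatureVector(float("nan"), 1, 0, 0.5, 1)
        with pytest.raises(InvariantError):
            FeatureVector(1, 1, 0, 1.5, 1)


class TestSelectCandidates:
    def _setup(self, rng):
        peaks = [Peak("c", i * 5000, i * 5000 + 400, 10, 10, rank=i + 1) for i in range(8)]
        junction_map = {}
        for i, p in enumerate(peaks):
            n = int(rng.integers(0, 4))
            junction_map[p] = [_jr(f"p{i}j{k}", "c", p.start + 50, "A" * 10) for k in range(n)]
        return peaks, junction_map

    def test_counts_match_junction_map_recount(self, rng):
        """Oracle: candidates are exactly the peaks with >= 1 junction unit."""
        for _ in range(10):
            peaks, junction_map = self._setup(rng)
            got = select_candidates(peaks, junction_map)
            want = {p for p in peaks if len(junction_map[p]) >= 1}
            assert {c.peak for c in got} == want
            for c in got:
                assert len(c.junction_reads) == len(junction_map[c.peak])

    def test_paired_units_are_fragments(self):
        p = Peak("c", 1000, 1400, 10, 10, rank=1)
        jrs = [_jr("f1/1", "c", 1050), _jr("f1/2", "c", 1050), _jr("f2/1", "c", 1051)]
        got = select_candidates([p], {p: jrs}, layout="paired")
        assert len(got) == 1
        # two distinct fragments despite three junction mates
        units = {j.read_id.rsplit("/", 1)[0] for j in got[0].junction_reads}
        assert len(units) == 2


class TestComputeFeatures:
    def test_known_values(self):
        peak = Peak("c", 100, 199, 2, 2, rank=1)
        alns = [_aln("a", "c", 100, 179, mm=0), _aln("b", "c", 120, 199, mm=4)]
        jrs = [_jr("j", "c", 150, "A" * 10)]
        fv = compute_features(peak, alns, jrs)
        assert fv.peak_width == 100.0
        assert fv.peak_depth == 2.0
        assert fv.variant_index == pytest.approx((0 + 4 / 80) / 2)
        assert fv.polya_purity == 1.0
        assert fv.junction_read_count == 1.0

    def test_empty_peak_rejected(self):
        peak = Peak("c", 100, 199, 0, 0, rank=1)
        with pytest.raises(InvariantError):
            compute_features(peak, [], [])


def _training_setup():
    """Six positive candidates at fixed-L1 3' ends, eight distal negatives."""
    copies = [L1Copy("c", i * 40_000, i * 40_000 + 6078, "+") for i in range(1, 7)]
    candidates = []
    for i, cp in enumerate(copies):
        peak = Peak("c", cp.three_prime_pos + 10, cp.three_prime_pos + 400, 30, 28, rank=i + 1)
        jrs = [_jr(f"c{i}j{k}", "c", peak.start + 5) for k in range(8)]
        from tipcall.scoring import CandidateCall

        c = CandidateCall(peak=peak, junction_reads=jrs)
        c.features = FeatureVector(390, 28, 0.002, 1.0, 8)
        candidates.append(c)
    negatives = {}
    for i in range(8):
        p = Peak("c", 300_000 + i * 15_000, 300_000 + i * 15_000 + 1500, 6, 4, rank=100 + i)
        negatives[p] = FeatureVector(1500, 4, 0.01, 0.0, 0)
    return copies, candidates, negatives


class TestTrainAndScore:
    def test_separable_training_and_determinism(self):
        copies, candidates, negatives = _training_setup()
        scorer = train_model(candidates, copies, peak_features=negatives, seed=7)
        assert scorer.n_positive == 6 and scorer.n_negative >= 5
        assert all(c.label == "known_positive" for c in candidates)
        scored = score_candidates(scorer, candidates)
        assert all(c.probability > 0.5 for c in scored)
        neg_fv = [fv for fv in negatives.values()]
        assert all(p < 0.5 for p in scorer.predict(neg_fv))
        scorer2 = train_model(candidates, copies, peak_features=negatives, seed=7)
        assert np.allclose(scorer.predict(neg_fv), scorer2.predict(neg_fv))

    def test_novel_candidate_scores_high(self):
        copies, candidates, negatives = _training_setup()
        scorer = train_model(candidates, copies, peak_features=negatives, seed=7)
        novel = FeatureVector(380, 25, 0.003, 0.95, 6)
        assert scorer.predict([novel])[0] > 0.5

    def test_too_few_labeled_rejected(self):
        copies, candidates, negatives = _training_setup()
        with pytest.raises(InvariantError):
            train_model(candidates[:2], copies, peak_features=negatives, seed=7)
        with pytest.raises(InvariantError):
            train_model(candidates, copies, peak_features={}, seed=7)

    def test_export_text_lists_features(self):
        copies, candidates, negatives = _training_setup()
        scorer = train_model(candidates, copies, peak_features=negatives, seed=7)
        text = scorer.export_text()
        for name in (
            "peak_width", "peak_depth", "variant_index", "polya_purity",
            "junction_read_count", "intercept",
        ):
            assert name in text

    def test_scoring_requires_features(self):
        from tipcall.scoring import CandidateCall

        copies, candidates, negatives = _training_setup()
        scorer = train_model(candidates, copies, peak_features=negatives, seed=7)
        bare = CandidateCall(peak=candidates[0].peak, junction_reads=[])
        with pytest.raises(InvariantError):
            score_candidates(scorer, [bare])
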