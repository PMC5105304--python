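"""Genome construction, implantation, CN/LOH events, and the read simulator."""

import numpy as np
import pytest

from tipcall.consensus import revcomp
from tipcall.errors import InvariantError
from tipcall.genome import (
    FIXED_L1_POLYA,
    CnLohSegment,
    PatientPair,
    TruthInsertion,
    apply_cn_loh,
    build_reference,
    build_sample_haplotypes,
    implant_insertion,
    implant_insertions,
    validate_segments,
)
from tipcall.simulate import find_anchor_sites, simulate_vectorette_reads

from conftest import random_seq


class TestBuildReference:
    def test_copies_written_at_annotated_coordinates(self, consensus):
        ref = build_reference(11, {"c1": 80_000, "c2": 60_000}, 3, consensus)
        assert len(ref.fixed_l1) == 3
        assert {len(s) for s in ref.chromosomes.values()} == {80_000, 60_000}
        for c in ref.fixed_l1:
            body = consensus.sequence + "A" * FIXED_L1_POLYA
            if c.strand == "-":
                body = revcomp(body)
            assert ref.chromosomes[c.chrom][c.start - 1 : c.end] == body

    def test_exclude_zones_respected(self, consensus):
        exclude = {"c1": [(30_000, 50_000)]}
        ref = build_reference(11, {"c1": 120_000}, 4, consensus, exclude=exclude)
        for c in ref.fixed_l1:
            assert c.end < 30_000 - 2000 or c.start > 50_000 + 2000

    def test_deterministic(self, consensus):
        a = build_reference(5, {"c": 50_000}, 1, consensus)
        b = build_reference(5, {"c": 50_000}, 1, consensus)
        assert a.chromosomes == b.chromosomes and a.fixed_l1 == b.fixed_l1

    def test_rejects_bad_args(self, consensus):
        with pytest.raises(InvariantError):
            build_reference(1, {"c": 0}, 1, consensus)
        with pytest.raises(InvariantError):
            build_reference(1, {"c": 1000}, -1, consensus)


def _spec(lo, tsd, strand="+", element=800, inv=0, polya=20, **kw):
    return TruthInsertion("c", lo + tsd - 1, lo, strand, element, inv, polya, tsd, **kw)


def _implant_ok(chroms, spec, consensus, rng, tries=40, **kw):
    """Implant at the first compatible site, shifting right on ambiguity."""
    from tipcall.errors import SiteIncompatibleError

    for shift in range(tries):
        trial = TruthInsertion(
            spec.chrom, spec.junction5 + shift, spec.junction3 + shift, spec.strand,
            spec.element_length, spec.inversion_length, spec.polya_length,
            spec.tsd_length, somatic=spec.somatic, sample_id=spec.sample_id,
            haplotype=spec.haplotype,
        )
        try:
            return implant_insertion(chroms, trial, consensus, **kw), trial
        except SiteIncompatibleError:
            continue
    raise AssertionError("no compatible site found")


class TestImplant:
    def test_growth_and_duplication(self, consensus, rng):
        chroms = {"c": random_seq(rng, 5000)}
        out, spec = _implant_ok(chroms, _spec(2000, 10), consensus, rng)
        assert len(out["c"]) == 5000 + spec.inserted_length
        lo, hi = spec.site_start, spec.site_end
        site = chroms["c"][lo - 1 : hi]
        # the duplicated site follows the inserted body
        assert out["c"][hi + spec.element_length + spec.polya_length : hi + spec.element_length + spec.polya_length + spec.tsd_length] == site
        # sequence outside the insertion is untouched
        assert out["c"][:hi] == chroms["c"][:hi]
        assert out["c"][-(5000 - hi):] == chroms["c"][hi:]

    def test_overlap_with_fixed_l1_rejected(self, consensus, rng):
        ref = build_reference(3, {"c": 40_000}, 1, consensus)
        c = ref.fixed_l1[0]
        spec = _spec(c.start + 10, 8)
        with pytest.raises(InvariantError):
            implant_insertion(ref.chromosomes, spec, consensus, fixed_l1=ref.fixed_l1)

    def test_out_of_bounds_rejected(self, consensus, rng):
        chroms = {"c": random_seq(rng, 1000)}
        with pytest.raises(InvariantError):
            implant_insertion(chroms, _spec(995, 10), consensus)

    def test_multiple_implants_coordinate_stable(self, consensus, rng):
        chroms = {"c": random_seq(rng, 20_000)}
        _, s1 = _implant_ok(chroms, _spec(4000, 8), consensus, rng)
        _, s2 = _implant_ok(chroms, _spec(15_000, 12, strand="-"), consensus, rng)
        out = implant_insertions(chroms, [s1, s2], consensus)
        assert len(out["c"]) == 20_000 + s1.inserted_length + s2.inserted_length
        # low-coordinate flank of the first implant is coordinate-stable
        assert out["c"][: s1.site_end] == chroms["c"][: s1.site_end]


class TestCnLoh:
    def test_segment_invariants(self):
        with pytest.raises(InvariantError):
            CnLohSegment("c", 10, 5, 2, True)
        with pytest.raises(InvariantError):
            CnLohSegment("c", 1, 10, 1, False)
        with pytest.raises(InvariantError):
            CnLohSegment("c", 1, 10, 3, True)
        with pytest.raises(InvariantError):
            validate_segments(
                [CnLohSegment("c", 1, 100, 2, True), CnLohSegment("c", 50, 200, 1, True)]
            )

    def _pair(self, consensus, rng):
        ref = build_reference(9, {"c": 60_000}, 1, consensus, exclude={"c": [(18_000, 42_000)]})
        _, germ = _implant_ok(ref.chromosomes, _spec(20_000, 9, sample_id="p"), consensus, rng)
        _, som = _implant_ok(
            ref.chromosomes,
            _spec(40_000, 7, element=600, sample_id="p", somatic=True),
            consensus, rng,
        )
        blood = build_sample_haplotypes(ref, [germ])
        tumor = build_sample_haplotypes(ref, [germ, som])
        return PatientPair("p", ref, blood, tumor, [germ, som]), germ, som

    def test_loh_removes_germline_from_tumor(self, consensus, rng):
        pair, germ, som = self._pair(consensus, rng)
        seg = CnLohSegment("c", germ.site_start - 1000, germ.site_end + 1000, 2, True)
        out = apply_cn_loh(pair, [seg], consensus)
        g = next(t for t in out.truth if not t.somatic)
        assert g.blood_only_loss and g.cn == "2" and g.loh == "Y"
        # tumor haplotypes carry only the somatic insertion
        assert len(out.tumor[1]["c"]) == 60_000 + som.inserted_length
        assert len(out.blood[1]["c"]) == 60_000 + germ.inserted_length
        s = next(t for t in out.truth if t.somatic)
        assert not s.blood_only_loss

    def test_segment_missing_insertion_is_noop(self, consensus, rng):
        pair, germ, _ = self._pair(consensus, rng)
        seg = CnLohSegment("c", 1, 100, 1, True)
        out = apply_cn_loh(pair, [seg], consensus)
        g = next(t for t in out.truth if not t.somatic)
        assert not g.blood_only_loss
        assert len(out.tumor[1]["c"]) > 60_000 + germ.inserted_length

    def test_homozygous_loss_rejected(self, consensus, rng):
        pair, germ, _ = self._pair(consensus, rng)
        germ.haplotype = "both"
        seg = CnLohSegment("c", germ.site_start, germ.site_end, 2, True)
        with pytest.raises(InvariantError):
            apply_cn_loh(pair, [seg], consensus)


@pytest.fixture(scope="module")
def ref(consensus):
    return build_reference(21, {"c": 60_000}, 1, consensus)


class TestSimulator:
    def test_anchor_sites_found_both_strands(self, consensus, rng):
        anchor = consensus.anchor
        seq = random_seq(rng, 3000) + anchor + random_seq(rng, 3000) + revcomp(anchor) + random_seq(rng, 1000)
        sites = find_anchor_sites({"c": seq}, consensus)
        assert (("c", 3000, "+") in sites) and (("c", 3000 + len(anchor) + 3000, "-") in sites)

    def test_reads_shape_and_determinism(self, consensus, ref):
        rs1, amps = simulate_vectorette_reads(ref.chromosomes, coverage=20, seed=3, consensus=consensus)
        rs2, _ = simulate_vectorette_reads(ref.chromosomes, coverage=20, seed=3, consensus=consensus)
        assert len(rs1) > 0
        assert [r.sequence for r in rs1.reads] == [r.sequence for r in rs2.reads]
        assert all(75 <= len(r.sequence) <= 100 for r in rs1.reads)
        assert len({r.id for r in rs1.reads}) == len(rs1.reads)
        assert any(a.kind == "l1" for a in amps)

    def test_amplicons_start_at_junction_flank(self, consensus, ref):
        _, amps = simulate_vectorette_reads(ref.chromosomes, coverage=10, seed=3, consensus=consensus)
        copy = ref.fixed_l1[0]
        l1_amps = [a for a in amps if a.kind == "l1"]
        assert len(l1_amps) == 6  # one per enzyme
        for a in l1_amps:
            # each amplicon extends from inside the element 3' end outward
            if a.strand == "+":
                assert a.start < copy.end < a.end or a.end <= copy.end
            else:
                assert a.start <= copy.start <= a.end or a.start >= copy.start

    def test_paired_layout(self, consensus, ref):
        rs, _ = simulate_vectorette_reads(
            ref.chromosomes, coverage=10, seed=4, consensus=consensus, layout="paired"
        )
        assert rs.layout == "paired"
        assert all(r.mate_sequence is not None for r in rs.reads)

    def test_off_target_and_background(self, consensus, ref):
        rs, amps = simulate_vectorette_reads(
            ref.chromosomes, coverage=10, seed=5, consensus=consensus,
            off_target_sites=[("c", 50_000, "+")], background_fraction=0.1,
        )
        assert any(a.kind == "off_target" for a in amps)
        base, _ = simulate_vectorette_reads(
            ref.chromosomes, coverage=10, seed=5, consensus=consensus,
            background_fraction=0.0,
        )
        assert len(rs) > len(base)

    def test_rejects_nonpositive_coverage(self, consensus, ref):
        with pytest.raises(InvariantError):
            simulate_vectorette_reads(ref.chromosomes, coverage=0, consensus=consensus)
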