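"""Hallmark measurement and allele parsing."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from tipcall.annotate import (
    AnnotatedInsertion,
    GeneModel,
    characterize_insertion,
    gene_overlap,
    measure_tsd,
)
from tipcall.consensus import default_consensus
from tipcall.errors import (
    InvariantError,
    NotL1InsertionError,
    SiteIncompatibleError,
)
from tipcall.genome import TruthInsertion, build_allele, implant_insertion

from conftest import random_seq


class TestMeasureTsd:
    def test_printed_pairs(self):
        assert measure_tsd(50488000, 50487984) == 17
        assert measure_tsd(33209876, 33209888) == 13
        assert measure_tsd(47881841, 47881832) == 10

    def test_symmetry(self):
        assert measure_tsd(100, 90) == measure_tsd(90, 100) == 11

    def test_adjacent(self):
        assert measure_tsd(5, 5) == 1

    def test_rejects_nonpositive(self):
        with pytest.raises(InvariantError):
            measure_tsd(0, 10)


def _implanted(consensus, rng, strand, element, inv, polya, tsd, flank=150, tries=40):
    """A filled allele and its empty site, at an implant-compatible position.

    Random flanks occasionally create boundary-ambiguous sites (the
    canonical parse then disagrees with the generating parameters);
    ``implant_insertion`` rejects those, exactly as genome construction
    does, so the fixture redraws flanks until a compatible site is found.
    """
    lo = flank - tsd // 2
    spec = TruthInsertion("c", lo + tsd - 1, lo, strand, element, inv, polya, tsd)
    for _ in range(tries):
        empty = random_seq(rng, 2 * flank)
        try:
            out = implant_insertion({"c": empty}, spec, consensus)
        except SiteIncompatibleError:
            continue
        return out["c"], empty
    raise AssertionError("no implant-compatible site found")


class TestCharacterize:
    def test_plus_strand_full(self, consensus, rng):
        allele, empty = _implanted(consensus, rng, "+", 2000, 0, 25, 12)
        p = characterize_insertion(allele, empty[:150], empty[150:], consensus)
        assert (p.strand, p.element_length, p.inversion_length, p.polya_length, p.tsd_length) == (
            "+", 2000, 0, 25, 12,
        )

    def test_minus_strand_with_inversion(self, consensus, rng):
        allele, empty = _implanted(consensus, rng, "-", 1839, 662, 30, 8)
        p = characterize_insertion(allele, empty[:150], empty[150:], consensus)
        assert (p.strand, p.element_length, p.inversion_length) == ("-", 1839, 662)

    def test_flank_split_is_immaterial(self, consensus, rng):
        allele, empty = _implanted(consensus, rng, "+", 900, 0, 12, 9)
        for cut in (20, 150, 200, 280):
            p = characterize_insertion(allele, empty[:cut], empty[cut:], consensus)
            assert p.element_length == 900 and p.tsd_length == 9

    def test_not_l1_rejected(self, consensus, rng):
        f5, f3 = random_seq(rng, 100), random_seq(rng, 100)
        with pytest.raises(NotL1InsertionError):
            characterize_insertion(f5 + random_seq(rng, 500) + f3, f5, f3, consensus)

    def test_shorter_allele_rejected(self, consensus, rng):
        f5, f3 = random_seq(rng, 100), random_seq(rng, 100)
        with pytest.raises(NotL1InsertionError):
            characterize_insertion((f5 + f3)[:150], f5, f3, consensus)


class TestGeneOverlap:
    GENES = [
        GeneModel("G1", "c1", 1000, 9000, "+", exons=((1000, 1200), (8800, 9000))),
        GeneModel("G2", "c1", 20000, 30000, "+", exons=()),
    ]

    def test_exon(self):
        ctx = gene_overlap("c1", 1100, self.GENES)
        assert (ctx.gene, ctx.feature) == ("G1", "exon")

    def test_intron(self):
        ctx = gene_overlap("c1", 5000, self.GENES)
        assert (ctx.gene, ctx.feature) == ("G1", "intron")

    def test_intergenic_nearest(self):
        ctx = gene_overlap("c1", 12000, self.GENES)
        assert ctx.feature == "intergenic"
        assert ctx.gene == "G1"
        assert ctx.distance == 3000

    def test_other_chrom(self):
        ctx = gene_overlap("c2", 5000, self.GENES)
        assert ctx.feature == "intergenic" and ctx.gene == "."

    def test_oracle_interval_scan(self, rng):
        """Exhaustive comparison against a brute-force interval scan."""
        genes = []
        for i in range(15):
            s = int(rng.integers(1, 90_000))
            e = s + int(rng.integers(100, 5000))
            ex = ((s, s + 50),) if rng.random() < 0.7 else ()
            genes.append(GeneModel(f"g{i}", "c", s, e, "+", exons=ex))
        for pos in rng.integers(1, 100_000, size=300):
            pos = int(pos)
            got = gene_overlap("c", pos, genes)
            containing = [g for g in genes if g.start <= pos <= g.end]
            if containing:
                assert got.feature in ("exon", "intron")
                exonic = [
                    g for g in containing
                    if any(s <= pos <= e for s, e in g.exons)
                ]
                assert (got.feature == "exon") == bool(exonic)
            else:
                assert got.feature == "intergenic"
                if genes:
                    best = min(
                        min(abs(pos - g.start), abs(pos - g.end)) for g in genes
                    )
                    assert got.distance == best


class TestAnnotatedInsertion:
    def test_tsd_invariant_enforced(self):
        with pytest.raises(InvariantError):
            AnnotatedInsertion(
                sample_id="s", chrom="c", junction5=100, junction3=90,
                strand="+", element_length=500, inversion_length=0,
                polya_length=10, tsd_length=5,
            )

    def test_partial_rows_skip_invariant(self):
        a = AnnotatedInsertion(
            sample_id="s", chrom="c", junction5=100, junction3=90,
            strand="+", element_length=None, inversion_length=None,
            polya_length=None, tsd_length=None, partially_specified=True,
        )
        assert a.tsd_length is None


@settings(max_examples=60, deadline=None)
@given(
    element=st.integers(min_value=60, max_value=6059),
    inv_frac=st.floats(min_value=0.0, max_value=0.95),
    tsd=st.integers(min_value=2, max_value=40),
    polya=st.integers(min_value=6, max_value=50),
    strand=st.sampled_from("+-"),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_implant_accepted_sites_round_trip(element, inv_frac, tsd, polya, strand, seed):
    """Any site the implanter accepts is recovered exactly by the parser.

    Implantation validates that the canonical parse of the realized allele
    equals the generating parameters, rejecting boundary-ambiguous flanks;
    this property pins down that contract for arbitrary parameter
    combinations, and additionally checks the parse regenerates the allele
    byte-for-byte.
    """
    cons = default_consensus()
    rng = np.random.default_rng(seed)
    inv = min(int(element * inv_frac), element - 1)
    lo = 150 - tsd // 2
    spec = TruthInsertion("c", lo + tsd - 1, lo, strand, element, inv, polya, tsd)
    allele = None
    for _ in range(8):
        empty = random_seq(rng, 300)
        try:
            allele = implant_insertion({"c": empty}, spec, cons)["c"]
            break
        except SiteIncompatibleError:
            continue
    assume(allele is not None)
    p = characterize_insertion(allele, empty[:150], empty[150:], cons)
    assert (p.strand, p.element_length, p.inversion_length, p.polya_length, p.tsd_length) == (
        strand, element, inv, polya, tsd,
    )
    parsed_spec = TruthInsertion(
        "c", p.tsd_start, p.tsd_end, p.strand, p.element_length,
        p.inversion_length, p.polya_length, p.tsd_length,
    )
    body = build_allele(parsed_spec, cons)
    dup = empty[p.tsd_start - 1 : p.tsd_end]
    rebuilt = empty[: p.tsd_end] + body + dup + empty[p.tsd_end :]
    assert rebuilt == allele
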