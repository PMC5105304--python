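"""Vectorette-PCR sequencing simulator.

Emulates the assay: genomic DNA is digested with a panel of restriction
enzymes, vectorette adapters are ligated, and PCR amplifies from a primer
anchored in the L1 3'UTR through the polyA tail into downstream flanking
DNA, stopping at the first downstream recognition site. Amplicons are then
sheared and sequenced as 75-100 bp reads. Because each enzyme yields a
different amplicon length from the same element end, per-base depth is
highest immediately adjacent to the junction and falls off in steps
downstream - the triangular pileup the caller exploits.

A configurable fraction of uniform background reads and a set of
"off-target" amplification sites (nonspecific PCR products, no L1
content) model the noise floor of the real assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Restriction
from Bio.Seq import Seq

from .consensus import L1Consensus, default_consensus, revcomp
from .errors import InvariantError
from .genome import Haplotype
from .rng import substream

log = logging.getLogger(__name__)

__all__ = [
    "Read",
    "ReadSet",
    "Amplicon",
    "DEFAULT_ENZYMES",
    "find_anchor_sites",
    "simulate_vectorette_reads",
]

DEFAULT_ENZYMES = ("AseI", "BspHI", "BstYI", "HindIII", "NcoI", "PstI")


@dataclass
class Read:
    id: str
    sequence: str
    quality: str
    mate_sequence: Optional[str] = None
    mate_quality: Optional[str] = None

    def __post_init__(self):
        if len(self.quality) != len(self.sequence):
            raise InvariantError("quality length != sequence length")
        if self.mate_sequence is not None and len(self.mate_quality or "") != len(
            self.mate_sequence
        ):
            raise InvariantError("mate quality length != mate sequence length")


@dataclass
class ReadSet:
    reads: List[Read]
    sample_id: str
    layout: str = "single"  # single | paired

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class Amplicon:
    """A truth amplicon: genomic span (1-based inclusive) plus sequence.

    ``sequence`` is written in element orientation (primer -> downstream
    flank); ``kind`` is 'l1' for anchor-primed products, 'off_target' for
    nonspecific products.
    """

    chrom: str
    start: int
    end: int
    strand: str
    enzyme: str
    sequence: str
    kind: str = "l1"


def find_anchor_sites(chroms: Haplotype, consensus: L1Consensus) -> List[Tuple[str, int, str]]:
    """All occurrences of the 3'UTR primer anchor, as (chrom, 0-based pos, strand)."""
    anchor = consensus.anchor
    anchor_rc = revcomp(anchor)
    sites = []
    for name in sorted(chroms):
        seq = chroms[name]
        for probe, strand in ((anchor, "+"), (anchor_rc, "-")):
            i = seq.find(probe)
            while i != -1:
                sites.append((name, i, strand))
                i = seq.find(probe, i + 1)
    return sites


def _first_cut(window: str, enzyme_name: str, min_offset: int) -> Optional[int]:
    enz = getattr(Restriction, enzyme_name)
    for pos in enz.search(Seq(window)):  # 1-based cut positions
        if pos - 1 >= min_offset:
            return pos - 1
    return None


def _l1_amplicons(
    chroms: Haplotype,
    consensus: L1Consensus,
    enzymes: Sequence[str],
    max_amplicon: int,
) -> List[Amplicon]:
    amplicons = []
    alen = consensus.anchor_len
    for chrom, pos, strand in find_anchor_sites(chroms, consensus):
        seq = chroms[chrom]
        if strand == "+":
            window = seq[pos : pos + max_amplicon]
        else:
            lo = max(0, pos + alen - max_amplicon)
            window = revcomp(seq[lo : pos + alen])
        for enzyme in enzymes:
            cut = _first_cut(window, enzyme, min_offset=alen + 1)
            if cut is None:
                log.info(
                    "no %s site within %d bp of anchor at %s:%d%s; amplicon truncated",
                    enzyme, max_amplicon, chrom, pos + 1, strand,
                )
                cut = len(window)
            amp = window[:cut]
            if strand == "+":
                start, end = pos + 1, pos + len(amp)
            else:
                start, end = pos + alen - len(amp) + 1, pos + alen
            amplicons.append(
                Amplicon(chrom=chrom, start=start, end=end, strand=strand,
                         enzyme=enzyme, sequence=amp, kind="l1")
            )
    return amplicons


def _off_target_amplicons(
    chroms: Haplotype,
    sites: Sequence[Tuple[str, int, str]],
    rng: np.random.Generator,
) -> List[Amplicon]:
    amplicons = []
    for chrom, pos, strand in sites:
        if chrom not in chroms:
            continue
        seq = chroms[chrom]
        length = int(rng.integers(800, 2500))
        if strand == "+":
            window = seq[pos : pos + length]
            start, end = pos + 1, pos + len(window)
        else:
            lo = max(0, pos - length)
            window = revcomp(seq[lo:pos])
            start, end = lo + 1, pos
        if len(window) < 200:
            continue
        amplicons.append(
            Amplicon(chrom=chrom, start=start, end=end, strand=strand,
                     enzyme=".", sequence=window, kind="off_target")
        )
    return amplicons


_QUAL = "I"


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if n == 0:
        return seq
    out = list(seq)
    for i in rng.choice(len(seq), size=n, replace=False):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def _reads_from_amplicon(
    amp_seq: str,
    depth: float,
    rng: np.random.Generator,
    error_rate: float,
    layout: str,
    read_len: Tuple[int, int],
    frag_len: int,
    frag_sd: int,
    insert_len: int,
    insert_sd: int,
) -> List[Tuple[str, Optional[str]]]:
    mean_rl = (read_len[0] + read_len[1]) / 2
    per_read_bases = mean_rl * (2 if layout == "paired" else 1)
    n = int(round(depth * len(amp_seq) / per_read_bases))
    out: List[Tuple[str, Optional[str]]] = []
    mean_f, sd_f = (insert_len, insert_sd) if layout == "paired" else (frag_len, frag_sd)
    for _ in range(n):
        fl = int(np.clip(rng.normal(mean_f, sd_f), 150, 900))
        fl = min(fl, len(amp_seq))
        start = int(rng.integers(0, len(amp_seq) - fl + 1))
        frag = amp_seq[start : start + fl]
        if layout == "paired":
            rl1 = int(rng.integers(read_len[0], read_len[1] + 1))
            rl2 = int(rng.integers(read_len[0], read_len[1] + 1))
            r1, r2 = frag[: min(rl1, fl)], revcomp(frag)[: min(rl2, fl)]
            if rng.random() < 0.5:
                r1, r2 = r2, r1
            out.append((_mutate(r1, rng, error_rate), _mutate(r2, rng, error_rate)))
        else:
            rl = min(int(rng.integers(read_len[0], read_len[1] + 1)), fl)
            r = frag[:rl] if rng.random() < 0.5 else revcomp(frag)[:rl]
            out.append((_mutate(r, rng, error_rate), None))
    return out


def simulate_vectorette_reads(
    chroms: Haplotype,
    enzymes: Sequence[str] = DEFAULT_ENZYMES,
    coverage: float = 30.0,
    error_rate: float = 0.002,
    seed: int = 0,
    layout: str = "single",
    consensus: Optional[L1Consensus] = None,
    background_fraction: float = 0.05,
    off_target_sites: Sequence[Tuple[str, int, str]] = (),
    off_target_depth_fraction: float = 0.2,
    sample_id: str = "sample",
    read_len: Tuple[int, int] = (75, 100),
    frag_len: int = 300,
    frag_sd: int = 30,
    insert_len: int = 450,
    insert_sd: int = 50,
    max_amplicon: int = 4000,
) -> Tuple[ReadSet, List[Amplicon]]:
    """Simulate one sample's vectorette reads from one haplotype.

    ``coverage`` is the target per-base depth adjacent to an L1 junction
    (summed over enzymes); each enzyme's amplicon is sampled at
    coverage/len(enzymes).
    """
    if coverage <= 0:
        raise InvariantError("coverage must be positive")
    cons = consensus or default_consensus()
    rng = substream(seed, "vectorette", sample_id)
    amplicons = _l1_amplicons(chroms, cons, enzymes, max_amplicon)
    amplicons += _off_target_amplicons(chroms, off_target_sites, rng)

    reads: List[Read] = []
    counter = 0

    def emit(pairs: List[Tuple[str, Optional[str]]]):
        nonlocal counter
        for seq1, seq2 in pairs:
            counter += 1
            reads.append(
                Read(
                    id=f"{sample_id}:r{counter}",
                    sequence=seq1,
                    quality=_QUAL * len(seq1),
                    mate_sequence=seq2,
                    mate_quality=None if seq2 is None else _QUAL * len(seq2),
                )
            )

    depth_per_enzyme = coverage / max(1, len(enzymes))
    for amp in amplicons:
        depth = coverage * off_target_depth_fraction if amp.kind == "off_target" else depth_per_enzyme
        emit(
            _reads_from_amplicon(
                amp.sequence, depth, rng, error_rate, layout,
                read_len, frag_len, frag_sd, insert_len, insert_sd,
            )
        )

    n_signal = len(reads)
    if background_fraction > 0 and n_signal:
        n_bg = int(round(background_fraction / (1 - background_fraction) * n_signal))
        names = sorted(chroms)
        lengths = np.array([len(chroms[n]) for n in names], dtype=float)
        p = lengths / lengths.sum()
        bg_pairs = []
        for _ in range(n_bg):
            name = names[int(rng.choice(len(names), p=p))]
            rl = int(rng.integers(read_len[0], read_len[1] + 1))
            if len(chroms[name]) <= rl:
                continue
            start = int(rng.integers(0, len(chroms[name]) - rl))
            seq = chroms[name][start : start + rl]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            if layout == "paired":
                bg_pairs.append((_mutate(seq, rng, error_rate), _mutate(revcomp(seq), rng, error_rate)))
            else:
                bg_pairs.append((_mutate(seq, rng, error_rate), None))
        emit(bg_pairs)

    return ReadSet(reads=reads, sample_id=sample_id, layout=layout), amplicons
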