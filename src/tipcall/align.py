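"""Read alignment to an L1-masked reference and to the element consensus.

The genome aligner is a deliberately simple, exhaustive-within-its-model
seed-and-extend mapper: exact k-mer seeds against a sorted index, ungapped
extension scoring substitutions, N never matching. With a per-read
mismatch allowance of floor(rate * len / 100) and allowed+1 disjoint
seed windows of length k, any qualifying placement retains at least one
error-free seed (pigeonhole), so the mapper provably finds every placement
within the allowance - which is what makes it testable against a
brute-force oracle. A read is 'unique' when exactly one qualifying
placement attains the best mismatch count and the runner-up qualifying
placement (if any) is at least ``margin`` mismatches worse; ties make it
'multi'. Only placements within the allowance enter this decision, so the
unique/multi verdict is a pure function of the genome and the read.

Element-level comparisons (consensus vs the L1 3' end + polyA template)
use Biopython's local PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .consensus import L1Consensus, revcomp
from .errors import InvariantError
from .genome import Haplotype, L1Copy

__all__ = [
    "ReadAlignment",
    "GenomeIndex",
    "mask_reference",
    "align_read",
    "align_reads",
    "L1Hit",
    "align_to_l1",
    "mismatch_allowance",
]

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def mismatch_allowance(length: int, rate: float = 3.0) -> int:
    """Allowed substitutions: floor(rate per 100 bp), scaled to read length."""
    return int(rate * length // 100)


@dataclass(frozen=True)
class ReadAlignment:
    """Best placement of one read; coordinates 1-based inclusive."""

    read_id: str
    chrom: Optional[str]
    start: Optional[int]
    end: Optional[int]
    strand: Optional[str]
    mismatches: Optional[int]
    status: str  # unique | multi | unmapped
    mate_id: Optional[str] = None

    def __post_init__(self):
        if self.status == "unmapped":
            if self.chrom is not None or self.start is not None:
                raise InvariantError("unmapped records carry no coordinates")
        else:
            if self.start is None or self.end is None or self.start > self.end:
                raise InvariantError("mapped record requires start <= end")


def mask_reference(chroms: Haplotype, annotation: Iterable) -> Haplotype:
    """Replace annotated L1 intervals with N, preserving lengths."""
    out = dict(chroms)
    for item in annotation:
        if isinstance(item, L1Copy):
            chrom, start, end = item.chrom, item.start, item.end
        else:
            chrom, start, end = item[0], int(item[1]), int(item[2])
        seq = out[chrom]
        if start < 1 or end > len(seq):
            raise InvariantError("annotation interval outside chromosome bounds")
        out[chrom] = seq[: start - 1] + "N" * (end - start + 1) + seq[end:]
    return out


class GenomeIndex:
    """Sorted exact k-mer index over a (masked) reference."""

    def __init__(self, chroms: Haplotype, k: int = 17):
        if k < 8 or k > 31:
            raise InvariantError("k must be in [8, 31]")
        self.k = k
        self.names = sorted(chroms)
        parts, offsets, pos = [], {}, 0
        sep = "N" * k
        for name in self.names:
            offsets[name] = pos
            parts.append(chroms[name])
            pos += len(chroms[name])
            parts.append(sep)
            pos += k
        self.offsets = offsets
        self.lengths = {n: len(chroms[n]) for n in self.names}
        self.genome = encode("".join(parts))
        g = self.genome
        n_kmers = len(g) - k + 1
        codes = np.zeros(n_kmers, dtype=np.uint64)
        invalid = (g >= 4).astype(np.int32)
        bad = np.cumsum(np.concatenate([[0], invalid]))
        window_bad = bad[k:] - bad[:-k]
        for j in range(k):
            codes = (codes << np.uint64(2)) | (g[j : j + n_kmers] & 3).astype(np.uint64)
        valid = window_bad == 0
        self._pos = np.nonzero(valid)[0].astype(np.int64)
        vcodes = codes[self._pos]
        order = np.argsort(vcodes, kind="stable")
        self._sorted_codes = vcodes[order]
        self._sorted_pos = self._pos[order]
        self._starts = np.array(
            [offsets[n] for n in self.names] + [len(g)], dtype=np.int64
        )

    def kmer_code(self, enc: np.ndarray) -> Optional[int]:
        if (enc >= 4).any():
            return None
        code = 0
        for b in enc:
            code = (code << 2) | int(b)
        return code

    def candidates(self, code: int) -> np.ndarray:
        # keep the key in the array's dtype: a Python int key forces numpy
        # onto a slow cross-dtype comparison path
        key = np.uint64(code)
        lo = np.searchsorted(self._sorted_codes, key, side="left")
        hi = np.searchsorted(self._sorted_codes, key, side="right")
        return self._sorted_pos[lo:hi]

    def to_local(self, gpos: int) -> Tuple[str, int]:
        """Global 0-based -> (chrom, 1-based start)."""
        idx = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        name = self.names[idx]
        return name, gpos - self.offsets[name] + 1


def _placements(
    enc_fwd: np.ndarray,
    enc_rev: np.ndarray,
    index: GenomeIndex,
    allowance: int,
) -> List[Tuple[int, int, str]]:
    """All (mismatches, global_start, strand) with mm <= allowance."""
    k = index.k
    L = len(enc_fwd)
    if L < k:
        return []
    windows = min(allowance + 1, L // k)
    offs = sorted({i * k for i in range(max(1, windows))} | {L - k})
    g = index.genome
    out = []
    seen = set()
    for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
        for off in offs:
            code = index.kmer_code(enc[off : off + k])
            if code is None:
                continue
            for p in index.candidates(code):
                start = int(p) - off
                if start < 0 or start + L > len(g):
                    continue
                key = (start, strand)
                if key in seen:
                    continue
                seen.add(key)
                mm = int(np.count_nonzero(g[start : start + L] != enc))
                if mm <= allowance:
                    out.append((mm, start, strand))
    return out


def align_read(
    read_id: str,
    seq: str,
    index: GenomeIndex,
    rate: float = 3.0,
    margin: int = 2,
    mate_id: Optional[str] = None,
) -> ReadAlignment:
    """Best ungapped placement of one read with unique/multi/unmapped status."""
    enc_f = encode(seq)
    enc_r = encode(revcomp(seq))
    allowance = mismatch_allowance(len(seq), rate)
    qual = _placements(enc_f, enc_r, index, allowance)
    if not qual:
        return ReadAlignment(read_id, None, None, None, None, None, "unmapped", mate_id)
    qual.sort(key=lambda p: (p[0], p[1], p[2]))
    best_mm, best_start, best_strand = qual[0]
    others = [p[0] for p in qual if (p[1], p[2]) != (best_start, best_strand)]
    runner = min(others) if others else None
    unique = (
        sum(1 for p in qual if p[0] == best_mm) == 1
        and (runner is None or runner - best_mm >= margin)
    )
    chrom, start = index.to_local(best_start)
    return ReadAlignment(
        read_id=read_id,
        chrom=chrom,
        start=start,
        end=start + len(seq) - 1,
        strand=best_strand,
        mismatches=best_mm,
        status="unique" if unique else "multi",
        mate_id=mate_id,
    )


def align_reads(
    reads,
    index: GenomeIndex,
    rate: float = 3.0,
    margin: int = 2,
) -> List[ReadAlignment]:
    """Align a ReadSet (or iterable of (id, seq)); paired mates align independently."""
    out = []
    items = getattr(reads, "reads", reads)
    for r in items:
        if isinstance(r, tuple):
            rid, seq = r
            out.append(align_read(rid, seq, index, rate, margin))
        else:
            if r.mate_sequence is None:
                out.append(align_read(r.id, r.sequence, index, rate, margin))
            else:
                out.append(align_read(r.id + "/1", r.sequence, index, rate, margin, mate_id=r.id + "/2"))
                out.append(align_read(r.id + "/2", r.mate_sequence, index, rate, margin, mate_id=r.id + "/1"))
    return out


# ---------------------------------------------------------------------------
# local alignment against the element


@dataclass(frozen=True)
class L1Hit:
    target_start: int  # 0-based, element/template coordinates
    target_end: int
    query_start: int
    query_end: int
    orientation: str  # + | -
    identity: float
    score: float


def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def align_to_l1(
    sequence: str,
    l1_consensus,
    min_identity: float = 0.9,
) -> Optional[L1Hit]:
    """Best local hit of ``sequence`` on the element (either orientation).

    ``l1_consensus`` may be an :class:`L1Consensus` or a plain template
    string (e.g. the 3' end + polyA template). Returns None when the best
    hit's identity is below ``min_identity``.
    """
    if not sequence:
        raise InvariantError("sequence must be non-empty")
    target = l1_consensus.sequence if isinstance(l1_consensus, L1Consensus) else str(l1_consensus)
    aligner = _local_aligner()
    best: Optional[L1Hit] = None
    for orientation, query in (("+", sequence), ("-", revcomp(sequence))):
        alns = aligner.align(target, query)
        if len(alns) == 0:
            continue
        aln = alns[0]
        counts = aln.counts()
        aligned_cols = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / aligned_cols if aligned_cols else 0.0
        hit = L1Hit(
            target_start=int(aln.aligned[0][0][0]),
            target_end=int(aln.aligned[0][-1][1]),
            query_start=int(aln.aligned[1][0][0]),
            query_end=int(aln.aligned[1][-1][1]),
            orientation=orientation,
            identity=identity,
            score=float(aln.score),
        )
        if best is None or hit.score > best.score:
            best = hit
    if best is None or best.identity < min_identity:
        return None
    return best
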