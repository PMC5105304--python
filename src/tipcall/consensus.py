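"""The active-subfamily L1 consensus element used throughout the package.

The element is a synthetic stand-in for the human-specific L1 (L1Hs)
consensus: a 6059 bp sequence (the length of the longest insertion the
pipeline is designed to recover) whose final ~160 bp play the role of the
3'UTR, carrying the 30 bp vectorette amplification-primer anchor. The
sequence is homopolymer-limited (no run of four or more identical bases)
so that the polyA tail appended by target-primed reverse transcription is
always the only long mononucleotide run at an insertion junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["L1Consensus", "default_consensus", "CONSENSUS_LENGTH"]

CONSENSUS_LENGTH = 6059
_ANCHOR_START = 5900  # 0-based; within the final 10% of the element
_ANCHOR_LEN = 30
_BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class L1Consensus:
    """Full-length element consensus plus the 3' amplification anchor."""

    sequence: str
    anchor_start: int = _ANCHOR_START  # 0-based start of primer anchor
    anchor_len: int = _ANCHOR_LEN
    polya_template_length: int = 30

    def __post_init__(self):
        if set(self.sequence) - set("ACGT"):
            raise ValueError("consensus sequence must contain only ACGT")
        if self.anchor_start < 0.9 * len(self.sequence) - 1e-9 or (
            self.anchor_start + self.anchor_len > len(self.sequence)
        ):
            raise ValueError("anchor interval must lie within the final 10% of the element")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def anchor(self) -> str:
        """The 3'UTR primer-anchor subsequence."""
        return self.sequence[self.anchor_start : self.anchor_start + self.anchor_len]

    def three_prime_template(self, tail: int = 500) -> str:
        """3' end of the element followed by a polyA stretch.

        This is the template consensus sequences are compared against when
        deciding whether a junction consensus carries element evidence.
        """
        return self.sequence[-tail:] + "A" * self.polya_template_length


def _limited_run_sequence(rng: np.random.Generator, length: int, max_run: int = 3) -> str:
    arr = rng.integers(0, 4, size=length)
    run = 1
    for i in range(1, length):
        if arr[i] == arr[i - 1]:
            run += 1
            if run > max_run:
                arr[i] = (arr[i] + 1 + rng.integers(0, 3)) % 4
                run = 1
        else:
            run = 1
    return "".join("ACGT"[b] for b in arr)


@lru_cache(maxsize=4)
def default_consensus(length: int = CONSENSUS_LENGTH, seed: int = 604211) -> L1Consensus:
    """Deterministic package-wide consensus element.

    The terminal base is forced to a non-A so the boundary between the
    element body and the polyA tail is identifiable, and the base 5' of
    the anchor region is left unconstrained otherwise.
    """
    rng = np.random.default_rng(seed)
    seq = _limited_run_sequence(rng, length)
    if seq[-1] == "A":
        seq = seq[:-1] + "G"
    return L1Consensus(sequence=seq)
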