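"""Hierarchical random-number streams.

A single master seed fans out into independent, named substreams so that
each stage (reference construction, implantation, read simulation per
sample, classifier negative sampling, ...) is reproducible on its own and
reruns of one stage never perturb another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_ints(keys: tuple) -> list[int]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode("utf-8")))
    return out


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys`` under ``seed``."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + _key_ints(tuple(keys)))
    return np.random.default_rng(ss)


def child_seed(seed: int, *keys) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + _key_ints(tuple(keys)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
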