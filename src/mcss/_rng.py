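"""Seed-substream helpers.

A single integer seed drives a whole simulation run.  Each module draws from
its own named substream so that changing the amount of randomness consumed in
one stage never perturbs another stage.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a generator deterministically derived from ``seed`` and ``label``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))])
    )


def as_seed(rng_or_seed) -> int:
    """Normalize an int seed or a Generator into a 31-bit integer seed."""
    if rng_or_seed is None:
        return 0
    if isinstance(rng_or_seed, (int, np.integer)):
        return int(rng_or_seed) & 0x7FFFFFFF
    if isinstance(rng_or_seed, np.random.Generator):
        return int(rng_or_seed.integers(0, 2**31))
    raise TypeError(f"expected int seed or numpy Generator, got {type(rng_or_seed)!r}")
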