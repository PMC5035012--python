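"""Seeded random-number plumbing.

A run owns one integer seed; every stage draws from a named substream so that
stage-level re-runs reproduce exactly regardless of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from (seed, name)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
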