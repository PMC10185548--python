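"""Deterministic random-stream management.

A single user-facing seed is fanned out into named substreams so that each
pipeline stage draws from its own reproducible stream regardless of which
other stages run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from (seed, stage name)."""
    return (int(seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))
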