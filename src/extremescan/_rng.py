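"""Seed handling.

One global integer seed expands to per-stage child generators through
``numpy.random.SeedSequence``: the child entropy is ``[seed, crc32(tag), ...]``
for a stage tag string, so every stage is reproducible in isolation and
stages never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(seed: int, *tags: str | int) -> np.random.SeedSequence:
    """Derive a stage-specific SeedSequence from a global integer seed."""
    entropy = [int(seed)]
    for tag in tags:
        entropy.append(tag if isinstance(tag, int) else zlib.crc32(tag.encode()))
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Generator for stage ``tags`` under global ``seed``."""
    return np.random.default_rng(child_seed_sequence(seed, *tags))
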