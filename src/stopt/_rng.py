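"""Deterministic random-stream derivation.

Every stochastic evaluation in the optimizer draws from a stream derived
from a tuple of integer keys (global seed, group key, node id, candidate
index, replicate index, metric key).  Streams are therefore reproducible
and independent of execution order, and a group receives bit-identical
noise whether it is optimized alone or co-scheduled with other groups.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np

_MASK32 = 0xFFFFFFFF


def name_key(*names: str) -> int:
    """Stable 32-bit key for a tuple of identifiers (CRC-32 of the joined names)."""
    return crc32("|".join(names).encode("utf-8"))


def derive_rng(seed: int, *keys: int) -> np.random.Generator:
    """Generator seeded from ``seed`` plus a tuple of integer sub-keys."""
    entropy = [int(seed) & _MASK32] + [int(k) & _MASK32 for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
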