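"""Hierarchical seeding.

One root seed is split into named, statistically independent child seeds so
that each stage (orientation maps, connectivity, stimuli, initial conditions,
spike generation) is independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(root_seed: int, name: str) -> int:
    """Derive a deterministic 31-bit child seed from a root seed and a label."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(root_seed: int, name: str) -> np.random.Generator:
    """Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(root_seed, name))
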