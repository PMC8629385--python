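"""Deterministic random-stream derivation.

Every stochastic operation in the toolkit draws from a substream derived
from one user-facing integer seed plus a string tag, so that stages can be
re-run independently yet reproduce the end-to-end pipeline bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *tags: str) -> np.random.Generator:
    """Return a Generator seeded from `seed` and a stable hash of `tags`."""
    words = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        words.append(zlib.crc32(tag.encode("utf8")) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))
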