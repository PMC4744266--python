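"""Named random substreams derived from one top-level seed.

Every stochastic component (initialization, rewiring, holdout sampling, ...)
draws from a generator keyed by the top-level seed plus a stable name, so
components can be re-seeded independently and whole runs reproduce
bit-identically from a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Generator for substream ``name`` (plus optional integer indices)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_key(name), *map(int, extra)))
    return np.random.default_rng(ss)
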