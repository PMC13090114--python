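"""Deterministic, label-addressed random streams.

Every stochastic operation derives its generator from a user seed plus a
tuple of string labels (e.g. ``("efficiency", "2022-05", "recorded")``), so
results are independent of evaluation order and reproducible bit-for-bit
under a fixed seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int | None, *labels) -> np.random.SeedSequence:
    key = tuple(zlib.crc32(str(label).encode("utf8")) for label in labels)
    if seed is None:
        return np.random.SeedSequence(spawn_key=key)
    return np.random.SeedSequence(entropy=int(seed), spawn_key=key)


def rng_for(seed: int | None, *labels) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *labels))
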