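"""Small shared numerics: link functions and seed derivation."""

from __future__ import annotations

import zlib

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def child_seed(seed: int, *tags: object) -> int:
    """Deterministic sub-seed < 2**31 derived from a base seed and context tags."""
    ss = np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, *(zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tags)]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, *tags: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *tags))
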