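"""Deterministic random-stream derivation.

Streams are keyed by (base_seed, *string keys) so that per-structure and
per-replicate simulations are reproducible and independent of evaluation
order: changing the set of structures or grid points never perturbs the draws
of another.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK31 = 0x7FFFFFFF


def seed_sequence(seed: int, *keys) -> np.random.SeedSequence:
    entropy = [int(seed) & _MASK31]
    entropy += [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.SeedSequence(entropy)


def rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(seed, *keys))
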