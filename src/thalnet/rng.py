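"""Deterministic per-stage random streams.

One root seed spawns independent generators keyed by stage name (and any
further qualifiers such as group, density or replicate index), so adding,
removing or reordering pipeline stages never perturbs the stream another
stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def stage_rng(seed: int, *keys) -> np.random.Generator:
    """Generator for stage ``keys`` under root ``seed``.

    ``stage_rng(seed, "permtest", "Lp", 3)`` is reproducible and independent
    of any other key tuple under the same root seed.
    """
    spawn_key = tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))
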