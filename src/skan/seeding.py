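"""Deterministic named random streams.

All randomness in the package flows from a single master seed through
named sub-streams, so any component can be re-run in isolation and two
runs with the same seed and configuration are bit-identical.  String keys
are folded to integers with CRC-32, then combined with the master seed in
a ``numpy.random.SeedSequence`` spawn key.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "spawn_seed"]


def _fold(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    if isinstance(key, (int, np.integer)) and key >= 0:
        return int(key)
    raise TypeError(f"stream keys must be strings or non-negative ints, got {key!r}")


def spawn_rng(master_seed: int, *keys) -> np.random.Generator:
    """Generator for the sub-stream named by ``keys`` under ``master_seed``."""
    ss = np.random.SeedSequence(int(master_seed),
                                spawn_key=tuple(_fold(k) for k in keys))
    return np.random.default_rng(ss)


def spawn_seed(master_seed: int, *keys) -> int:
    """A plain integer seed (< 2**31) derived from a named sub-stream."""
    return int(spawn_rng(master_seed, *keys).integers(0, 2**31 - 1))
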