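"""Deterministic fan-out of a single user seed into per-stage streams.

A stage name is hashed with CRC32 (stable across platforms and Python
versions) and combined with the root seed into a ``SeedSequence`` so that
every pipeline stage gets an independent, reproducible stream and adding a
new stage never perturbs the streams of existing ones.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(root_seed: int, *keys: str | int) -> np.random.SeedSequence:
    """Build a ``SeedSequence`` for a named (and optionally indexed) stage."""
    entropy = [int(root_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode("utf-8")))
        else:
            entropy.append(int(k) & 0xFFFFFFFF)
    return np.random.SeedSequence(entropy)


def stage_rng(root_seed: int, *keys: str | int) -> np.random.Generator:
    """Generator seeded from :func:`stage_seed`."""
    return np.random.default_rng(stage_seed(root_seed, *keys))
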