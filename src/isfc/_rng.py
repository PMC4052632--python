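"""Seed-substream plumbing: one top-level seed, named per-stage streams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic, stage-named RNG derived from a single top-level seed.

    Different names give statistically independent streams; the same
    (seed, name) pair always yields the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
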