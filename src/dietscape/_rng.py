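"""Seed-stream management.

Every stochastic operation draws from its own RNG stream, derived from a
master seed plus the operation's name, so that individual pipeline stages
are reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The same (seed, name) pair always yields an identical stream; different
    names yield statistically independent streams for the same master seed.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
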