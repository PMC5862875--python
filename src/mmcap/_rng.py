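"""Seed plumbing: one root seed, named substreams per pipeline stage.

Every generator in the package draws from ``substream(seed, name)`` so that
stages are individually reproducible: rerunning only the survival simulation
with the same root seed gives byte-identical output regardless of whether the
depth simulation ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a root seed.

    The substream key is a CRC32 of the name, so streams are stable across
    sessions and independent of call order.
    """
    if not (0 <= int(seed) < 2**31):
        raise ValueError(f"seed must be in [0, 2^31), got {seed}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
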