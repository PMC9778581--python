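"""Seed plumbing: every random draw in the package flows from named seeds."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_for"]


def seed_for(base_seed: int, *tags) -> int:
    """Derive a deterministic child seed from a base seed and string tags.

    The same ``(base_seed, *tags)`` always yields the same child, children for
    distinct tags are effectively independent, and the result fits in a signed
    32-bit integer.
    """
    parts = [int(base_seed) & 0x7FFFFFFF]
    for t in tags:
        parts.append(zlib.crc32(str(t).encode("utf8")))
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
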