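"""Deterministic seed derivation.

A single master seed fans out to per-stage / per-run / per-fold seeds so that
repeated evaluations differ in a controlled, reproducible way. Derived seeds
stay below 2**31 so they are valid for every RNG API in the stack.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(master: int, *tags: object) -> int:
    """Derive a child seed from ``master`` and an arbitrary tag sequence.

    Tags may be strings or integers; strings are hashed with CRC32 so the
    derivation is stable across processes and Python versions.
    """
    words = [int(master) % _MOD]
    for t in tags:
        if isinstance(t, (int, np.integer)):
            words.append(int(t) % _MOD)
        else:
            words.append(zlib.crc32(str(t).encode()) % _MOD)
    ss = np.random.SeedSequence(words)
    return int(ss.generate_state(1)[0] % _MOD)


def rng_for(master: int, *tags: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *tags))
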