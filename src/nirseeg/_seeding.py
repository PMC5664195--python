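"""Deterministic expansion of one master seed into named child streams.

Every stochastic component takes its randomness from a child stream derived
from (master seed, context keys), so a full experiment is reproducible from a
single integer and changing one stage's keys never perturbs another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed(master: int, *keys: object) -> int:
    """Derive a deterministic 31-bit seed from a master seed and context keys."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(master: int, *keys: object) -> np.random.Generator:
    """A Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *keys))
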