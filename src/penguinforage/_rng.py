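"""Deterministic seed plumbing.

Every stochastic stage receives its own child stream derived from the
master seed and a stable string key, so adding a stage never perturbs the
streams of earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, int):
        return key
    return zlib.crc32(key.encode("utf-8"))


def child_seed(master: int, *keys: str | int) -> np.random.SeedSequence:
    """Derive a reproducible child SeedSequence from a master seed and keys."""
    return np.random.SeedSequence([int(master)] + [_key_to_int(k) for k in keys])


def child_rng(master: int, *keys: str | int) -> np.random.Generator:
    """A Generator seeded from ``child_seed(master, *keys)``."""
    return np.random.default_rng(child_seed(master, *keys))
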