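"""Stable derivation of per-entity random streams from one master seed.

Every source of randomness in the package funnels through ``derived_rng``:
the stream for (seed, *labels) depends only on the master seed and the labels,
never on call order, so adding a sample to a simulation leaves every existing
sample's counts bit-identical.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derived_rng", "stable_key"]


def stable_key(*labels) -> int:
    """Deterministic 63-bit integer key for a tuple of string-able labels."""
    digest = hashlib.sha256("\x1f".join(str(x) for x in labels).encode()).digest()
    return int.from_bytes(digest[:8], "big") >> 1


def derived_rng(seed: int, *labels) -> np.random.Generator:
    """Generator for the stream identified by ``labels`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stable_key(*labels)]))
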