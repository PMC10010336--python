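"""Named random streams derived from one global seed.

Each pipeline stage draws from its own stream keyed by a stable string, so
adding a stage (or reordering stages) never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "stream_seed"]


def _key(name: str) -> int:
    # stable across processes (unlike hash())
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stream `name` under global `seed`."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _key(name)]))


def stream_seed(seed: int, name: str) -> int:
    """A derived 31-bit integer seed (for libraries that take plain ints)."""
    return int(stream(seed, name).integers(0, 2**31 - 1))
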