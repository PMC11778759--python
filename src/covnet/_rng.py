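"""Named random substreams.

A single user-facing seed is fanned out into independent, order-insensitive
substreams so that each pipeline stage (bootstrap, CV folds, simulation,
test split) can be rerun in isolation and still reproduce exactly.  The
split is ``SeedSequence(seed, spawn_key=(crc32(name), ...))``: the spawn
key is a stable hash of the human-readable stream name, so adding a new
stream never perturbs existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return the named child generator of a root seed."""
    key = tuple(zlib.crc32(str(n).encode("utf8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def subseed(seed: int, *names: object) -> int:
    """Derive a plain integer seed (< 2**31) from a named substream."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
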