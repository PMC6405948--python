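"""Named substreams derived from one master seed.

Every stochastic stage draws from its own substream keyed by a stable string,
so enabling, disabling or reordering one stage never perturbs the draws of
another. Keys are hashed with CRC32 (stable across platforms and Python
versions, unlike ``hash``) and folded into a :class:`numpy.random.SeedSequence`
together with the master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_int"]


def _key_to_int(key: object) -> int:
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    The same ``(seed, keys)`` pair always yields an identically-seeded
    generator; distinct key tuples yield statistically independent streams.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def spawn_int(seed: int, *keys: object) -> int:
    """A 31-bit integer seed for libraries that take ``random_state`` ints."""
    return int(substream(seed, *keys).integers(0, 2**31 - 1))
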