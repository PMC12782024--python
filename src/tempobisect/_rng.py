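"""Seeded, named random substreams.

All randomness in the package flows from one root seed through named
substreams so that each stage (scheduling, responses, ratings, volumes)
is independently reproducible: ``substream(seed, "responses/p07")`` always
yields the same generator regardless of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """A ``numpy`` Generator for the (root seed, stream name) pair."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(tag,))
    return np.random.default_rng(ss)
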