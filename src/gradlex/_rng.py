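"""Named, reproducible random substreams.

Every source of randomness in the package derives from a single integer seed
through a named substream, so that identical seeds give identical outputs and
independent stages draw from statistically independent streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of master `seed`.

    The stream key is a CRC32 of the name, so the mapping is stable across
    processes and Python versions (unlike the builtin ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
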