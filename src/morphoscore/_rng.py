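"""Named substream seeding.

All randomness in the package flows from one top-level integer seed.  Each
stage draws from a named substream derived from (seed, name) so that any stage
can be regenerated independently of the others and adding a stage never
perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` of top-level `seed`.

    The substream key is a CRC32 of the name, so it is stable across Python
    processes (unlike the built-in hash).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
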