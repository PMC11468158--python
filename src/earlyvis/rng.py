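"""Reproducible random-stream management.

All randomness in the package flows from a single integer master seed.
Independent purposes (stimulus synthesis, train/test splitting, resampling,
per-presentation transforms, background noise, weight initialization) draw
from named substreams so that each component is reproducible in isolation:
changing how many draws one component makes never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"substream keys must be int or str, got {type(key).__name__}")


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    ``keys`` may mix strings (purpose names, hashed stably via CRC32) and
    integers (indices such as run or image number). The same
    ``(master_seed, keys)`` always yields an identical stream.
    """
    entropy = [int(master_seed)] + [_key_to_int(k) for k in keys]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
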