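"""Seed plumbing: every random draw in the package flows through one of these."""
from __future__ import annotations

import zlib

import numpy as np


def as_rng(rng) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def stage_rng(seed: int, *tokens) -> np.random.Generator:
    """Generator for one named pipeline stage.

    The stage name is folded into the seed via CRC32 so that stages draw from
    independent streams while remaining fully reproducible from one integer.
    """
    label = "/".join(str(t) for t in tokens)
    h = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))
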