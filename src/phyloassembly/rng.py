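"""Deterministic seed splitting.

A single global seed is split into independent substreams keyed by stable
stage names, so adding or disabling one pipeline stage never perturbs the
randomness another stage sees.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(seed: int, name: str) -> int:
    """A stable 31-bit child seed for stage ``name`` under global ``seed``."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for stage ``name`` derived from the global ``seed``."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return np.random.default_rng(ss)
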