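"""Small shared helpers."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed survey tables).

    Python's built-in ``round`` uses banker's rounding, which would turn
    29.5% into 30% or 28% depending on parity; report tables always round
    half up.
    """
    q = Decimal(1).scaleb(-ndigits)
    r = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return int(r) if ndigits <= 0 else r


def stable_hash(text: str) -> int:
    """Platform-independent 32-bit hash used to derive per-group RNG streams."""
    return zlib.crc32(text.encode("utf-8"))


def rng_for(seed: int, *keys) -> np.random.Generator:
    """Deterministic generator derived from a base seed plus stream keys.

    String keys are CRC32-hashed so the stream is stable across platforms
    and Python hash randomization.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        ints.append(stable_hash(k) if isinstance(k, str) else int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))
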