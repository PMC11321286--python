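"""Seeding and rounding helpers used across the package.

One master seed drives every stage through named substreams so that cohort
generation, validation sampling and bootstrap resampling are independently
reproducible: changing how many bootstrap draws one stage takes never
perturbs another stage's stream.
"""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is derived from a CRC32 of the name, so the mapping is
    stable across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed percentages).

    Python's built-in ``round`` is banker's rounding; reported whole-percent
    figures use half-up instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(x: float) -> int:
    """Express a proportion as a whole percentage, rounded half-up."""
    return int(round_half_up(100.0 * x))
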