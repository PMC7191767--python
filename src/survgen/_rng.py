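"""Seed-stream discipline.

One master seed per run; every generation stage (survival times, censoring,
nominal biomarker, numeric biomarker, each random attribute) draws from its
own child stream keyed by a stable name.  Adding or reordering attributes
therefore never perturbs the survival times, and per-attribute streams mean
reordering the attribute list permutes but does not change each attribute's
values.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """Return a generator for the child stream identified by ``names``.

    The spawn key is derived from a CRC-32 of each name, so the stream
    depends only on the master seed and the stage name, never on the order
    in which stages are set up.
    """
    key = tuple(zlib.crc32(name.encode("utf-8")) for name in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))
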