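"""Deterministic named seed streams.

Every stochastic stage derives its own stream from the single master seed
plus a tuple of string/int labels (stage name, group, time point, replicate
index, ...).  Adding a new stage therefore never shifts the draws of an
existing one, and two runs with the same master seed are bit-identical.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK31 = 0x7FFFFFFF


def seed_sequence(master: int, *labels) -> np.random.SeedSequence:
    """SeedSequence keyed by a master seed and a label path."""
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    return np.random.SeedSequence(entropy=int(master) & _MASK31, spawn_key=key)


def rng_for(master: int, *labels) -> np.random.Generator:
    """A numpy Generator for the given label path."""
    return np.random.default_rng(seed_sequence(master, *labels))


def int_seed(master: int, *labels) -> int:
    """A 31-bit integer seed for code that takes plain int seeds."""
    return int(seed_sequence(master, *labels).generate_state(1)[0]) & _MASK31
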