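"""Deterministic seed derivation.

All randomness in a run flows from one master seed.  Child generators are
derived from ``(master_seed, crc32(label))`` so that every module draws from
an independent, reproducible stream and adding a new consumer never perturbs
the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stream ``label`` derived from ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _label_key(label)]))


def child_seed(seed: int, label: str) -> int:
    """A derived integer seed below 2**31, for APIs that take plain ints."""
    ss = np.random.SeedSequence([int(seed), _label_key(label)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
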