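"""Deterministic labelled random substreams.

All randomness in the package flows from one master seed; each stage pulls
an independent generator keyed by a string label so that adding or removing
a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator derived deterministically from ``seed`` + labels."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(lab).encode()) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def subseed(seed: int, *labels: object) -> int:
    """A plain integer seed (< 2**31) derived from ``seed`` + labels."""
    return int(rng_for(seed, *labels).integers(0, 2**31 - 1))
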