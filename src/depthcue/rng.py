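"""Deterministic random-stream derivation.

Every simulator takes a root seed; per-condition streams are derived by
stably hashing condition labels into a :class:`numpy.random.SeedSequence`,
so adding or reordering conditions never perturbs the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _label_entropy(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Generator for the stream identified by ``seed`` and a label path."""
    entropy = [int(seed)] + [_label_entropy(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *labels: str) -> int:
    """A child integer seed (< 2**31) for the given label path."""
    entropy = [int(seed)] + [_label_entropy(lab) for lab in labels]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
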