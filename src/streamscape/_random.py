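"""Deterministic seed fan-out.

One global seed is expanded into independent per-stage seeds by hashing the
stage label, so each pipeline stage is reproducible in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, label: str) -> int:
    """Derive a stage seed (< 2**31) from a global seed and a label."""
    digest = hashlib.sha256(f"{int(global_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def rng_for(global_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, label))
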