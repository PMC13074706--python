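"""Deterministic, named seed derivation.

All randomness in the package flows from one integer seed.  Sub-streams are
derived by hashing the parent seed together with a human-readable name, so
adding a new consumer never perturbs existing streams and no global RNG
state is involved.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "spawn"]


def child_seed(seed: int, *names: object) -> int:
    """Derive a stable 31-bit child seed from ``seed`` and a name path."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:4], "big") & 0x7FFFFFFF


def spawn(seed: int, *names: object) -> np.random.Generator:
    """A ``numpy`` generator for the named sub-stream of ``seed``."""
    return np.random.default_rng(child_seed(seed, *names))
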