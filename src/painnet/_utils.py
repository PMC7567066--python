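"""Small shared helpers: deterministic seed derivation and validation."""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31


def derive_seed(master: int, *keys) -> int:
    """Derive a stable sub-seed (< 2**31) from a master seed and string keys.

    Uses SHA-256 on the textual key so the derivation is independent of
    Python's per-process hash randomization and of platform word size.
    """
    text = ":".join([str(int(master))] + [str(k) for k in keys])
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % _MOD


def check_finite_2d(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x
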