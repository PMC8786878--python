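"""Small shared helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from arbitrary hashable tags.

    Order of tags matters; the derivation is independent of Python's hash
    randomization so it is stable across processes.
    """
    h = hashlib.sha256(repr(parts).encode("utf-8")).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def as_label_array(x) -> np.ndarray:
    arr = np.asarray(x).ravel()
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, False, True}:
        raise ValueError("labels must be binary 0/1")
    return arr.astype(float)
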