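"""Deterministic sub-stream random generators.

A single global seed fans out to per-unit substreams keyed by arbitrary
hashables (strain, resource, level, replicate, ...) so that regenerating a
subset of the data reproduces exactly the same draws.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _key_digest(*keys: object) -> list[int]:
    h = hashlib.sha256()
    for k in keys:
        if isinstance(k, float) and k == int(k):
            k = int(k)  # 5.0 and 5 address the same stream
        h.update(repr(k).encode("utf8"))
        h.update(b"\x1f")
    d = h.digest()
    return [int.from_bytes(d[i : i + 4], "little") for i in range(0, 16, 4)]


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for stream `keys` under global `seed`.

    Stable across processes and platforms (no reliance on PYTHONHASHSEED).
    """
    ss = np.random.SeedSequence([int(seed), *_key_digest(*keys)])
    return np.random.default_rng(ss)
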