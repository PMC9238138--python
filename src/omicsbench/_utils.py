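"""Shared helpers: deterministic seed derivation and small validators."""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31


def child_seed(master: int, *names: object) -> int:
    """Derive a reproducible child seed from a master seed and a name path.

    Components are regenerable independently: the child seed depends only on
    the master seed and the (stringified) name path, never on call order.
    Result is always in [0, 2**31).
    """
    key = "|".join(str(x) for x in (master, *names))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % _MOD


def rng_for(master: int, *names: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *names))


def check_proportions(pairs, field: str) -> None:
    total = float(sum(p for _, p in pairs))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{field}: proportions sum to {total!r}, expected 1.0")
    if any(p < 0 for _, p in pairs):
        raise ValueError(f"{field}: negative proportion")
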