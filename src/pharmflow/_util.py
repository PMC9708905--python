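"""Shared helpers: deterministic child-seed derivation and hashing."""

from __future__ import annotations

import numpy as np

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


def fnv1a_64(data: bytes | str) -> int:
    """FNV-1a 64-bit hash. Deterministic across platforms and runs."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


def child_seed(seed: int, component: str) -> int:
    """Derive a per-component child seed from a global seed.

    The derivation is ``fnv1a_64(component) XOR seed`` folded to 32 bits, so
    each pipeline stage can be regenerated independently from the global seed
    and its component name alone.
    """
    return (fnv1a_64(component) ^ (seed & _MASK64)) & 0xFFFFFFFF


def child_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, component))
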