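"""Shared helpers: seeding and small numeric utilities."""

from __future__ import annotations

import numpy as np

_SEED_MOD = 2**31  # keep derived seeds in the int32-safe range


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a single integer seed.

    Uses :class:`numpy.random.SeedSequence` spawning, so children are
    statistically independent of each other and of the parent stream.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % _SEED_MOD) for c in children]


def as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
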