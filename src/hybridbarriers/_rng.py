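"""Seed handling: one root seed, independent child streams per operation."""
from __future__ import annotations

import numpy as np

__all__ = ["rng_from", "child_seeds"]


def rng_from(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; pass through an existing one unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]
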