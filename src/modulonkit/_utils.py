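"""Shared helpers: seed fan-out, small validation utilities."""

from __future__ import annotations

import numpy as np

MAX_SEED = 2**31 - 1


def spawn_seeds(master_seed: int, n: int, salt: str = "") -> list[int]:
    """Derive ``n`` child seeds (< 2**31) deterministically from a master seed.

    A stable string salt separates independent consumers of the same master
    seed (e.g. the ICA restarts vs. the noise generator) so that adding a new
    consumer never perturbs an existing stream.
    """
    entropy = [master_seed] + [ord(c) for c in salt]
    ss = np.random.SeedSequence(entropy)
    return [int(s) % MAX_SEED for s in ss.generate_state(n, dtype=np.uint64)]


def rng_from(seed: int, salt: str = "") -> np.random.Generator:
    return np.random.default_rng(spawn_seeds(seed, 1, salt)[0])


def check_positive_int(name: str, value: int) -> None:
    if not isinstance(value, (int, np.integer)) or value <= 0:
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
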