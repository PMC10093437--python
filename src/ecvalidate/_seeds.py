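"""Deterministic seed derivation.

Every source of randomness in the package is keyed off one master seed via
numpy's SeedSequence spawn-key mechanism, so any repetition, down-sampling
draw or bootstrap window can be re-run in isolation from (master, path).
"""

from __future__ import annotations

import numpy as np

_MAX_SEED = 2**31  # derived seeds stay below 2^31 so they fit any RNG API


def derive_seed(master_seed: int, *path: int) -> int:
    """Return a deterministic child seed for the given integer path.

    The same (master_seed, path) always yields the same value; distinct paths
    yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1)[0] % _MAX_SEED)


def derive_rng(master_seed: int, *path: int) -> np.random.Generator:
    """A Generator seeded from ``derive_seed(master_seed, *path)``."""
    return np.random.default_rng(derive_seed(master_seed, *path))
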