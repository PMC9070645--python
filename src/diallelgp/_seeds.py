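"""Deterministic seed derivation.

Every stochastic stage derives its RNG from (master_seed, stage_label), so adding a
stage never perturbs the randomness of earlier stages.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def derive_seed(master_seed: int, label: str) -> int:
    """A stable 31-bit child seed for a named stage."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """Generator seeded from the master seed and a stage label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    )
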