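"""Deterministic seed tree: every stochastic stage derives its generator from the
global seed plus a stage label, so pipelines are reproducible end to end."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng", "as_rng"]


def stage_seed(global_seed: int, label: str) -> int:
    """A stable 31-bit seed for a named stage."""
    return (int(global_seed) * 2654435761 + zlib.crc32(label.encode())) % (2**31 - 1)


def stage_rng(global_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, label))


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
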