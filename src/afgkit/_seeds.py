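"""Hierarchical, named seed fan-out.

Every stochastic entry point in the package takes a ``numpy.random.Generator``.
Sub-experiments (participant -> task -> run -> trial) derive child generators
from one master seed through :func:`spawn_rng`, so any branch of a session is
independently reproducible without replaying the branches before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "child_seed"]


def _hash_component(component: object) -> int:
    return zlib.crc32(str(component).encode("utf-8"))


def child_seed(master_seed: int, *path: object) -> np.random.SeedSequence:
    """Derive a named child ``SeedSequence`` from ``master_seed``.

    ``path`` components (strings or ints) are hashed individually, so
    ``child_seed(s, "battery", "afg_fixed", 0)`` is stable across sessions
    and independent of any other path.
    """
    if not (0 <= int(master_seed) < 2**63):
        raise ValueError("master_seed must be a non-negative integer")
    key = tuple(_hash_component(c) for c in path)
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)


def spawn_rng(master_seed: int, *path: object) -> np.random.Generator:
    """Return a ``Generator`` seeded from a named branch of the master seed."""
    return np.random.default_rng(child_seed(master_seed, *path))
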