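"""Named, independent random streams derived from one master seed.

Every stochastic component (founders, allelic effects, climate, mating,
dispersal, thinning, ...) draws from its own stream so components can be
tested in isolation and a run is bit-reproducible from the master seed alone.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "spawn_key"]


def spawn_key(*path: int | str) -> tuple[int, ...]:
    """Map a path of names/indices to a stable integer spawn key."""
    return tuple(
        int(p) if isinstance(p, (int, np.integer)) else zlib.crc32(str(p).encode())
        for p in path
    )


def stream(master_seed: int, *path: int | str) -> np.random.Generator:
    """Return the generator for the stream named by ``path``.

    The same ``(master_seed, path)`` always yields the same stream, and
    streams with different paths are statistically independent.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=spawn_key(*path))
    return np.random.default_rng(ss)
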