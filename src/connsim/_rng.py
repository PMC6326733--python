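"""Deterministic RNG substream management.

All stochastic code in the package draws from :class:`numpy.random.Generator`
instances derived from a single master seed via ``SeedSequence.spawn``-style
keyed children. Keying substreams on ``(seed, *labels)`` (a counter-based
split) makes every replication and subject independently re-creatable and
keeps results invariant to execution order or parallelism.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream", "child_seed"]


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    Distinct key tuples yield statistically independent streams; identical
    tuples always yield identical streams.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in keys))
    return np.random.Generator(np.random.PCG64(ss))


def child_seed(seed: int, *keys: int) -> int:
    """Derive a 31-bit integer seed for external consumers (e.g. kernels)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
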