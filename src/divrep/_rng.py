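"""Deterministic RNG substreams.

Every stochastic step in the package draws from a generator keyed by a
top-level integer seed plus a tuple of small non-negative integers naming the
work unit (e.g. ``(STREAM_MATRIX, n, member_index)``).  Substreams are
independent of evaluation order, so changing a set size or scan range never
reshuffles earlier members and results are identical regardless of scheduling.
"""

from __future__ import annotations

import numpy as np

# Leading tags keep key spaces of different subsystems disjoint.
STREAM_MATRIX = 0      # random matrix sets Q(n)
STREAM_SHUFFLE = 1     # Monte-Carlo sequence shuffles
STREAM_SIMULATE = 2    # artificial benchmark sequences
STREAM_CLASSIFY = 3    # matrix-element shuffles for cut significance


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a generator for the work unit named by ``key`` under ``seed``."""
    entropy = int(seed)
    if entropy < 0:
        raise ValueError("seed must be non-negative")
    spawn_key = tuple(int(k) for k in key)
    if any(k < 0 for k in spawn_key):
        raise ValueError("substream key parts must be non-negative")
    return np.random.default_rng(np.random.SeedSequence(entropy, spawn_key=spawn_key))
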