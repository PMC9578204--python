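"""Hierarchical random-number streams.

Every stage of an experiment draws from a child stream derived
deterministically from one master seed and a structured key (purpose code,
simulation index, ...).  Parallel or reordered execution therefore cannot
change any result, and every stream can be reconstructed from the manifest.
"""

from __future__ import annotations

import numpy as np

# Purpose codes for spawn keys. Stable across versions: changing them
# changes every downstream stream.
PURPOSE_FEATURE_SPECS = 0
PURPOSE_DATA = 1
PURPOSE_FOLDS = 2
PURPOSE_MCCV = 3
PURPOSE_CLASSIFIER = 4
PURPOSE_SUBSAMPLE = 5


def child_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Return a generator for the stream identified by ``key`` under ``master_seed``."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


def child_seed(master_seed: int, *key: int) -> int:
    """A 31-bit integer seed for libraries that take plain ints (e.g. sklearn)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, ``None`` or an existing Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
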