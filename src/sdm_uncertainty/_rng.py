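"""Named child random streams off a single master seed.

Every stochastic component draws from its own child of the master
``SeedSequence`` so that, e.g., adding species does not shift the climate
draws.  Stream names map to fixed spawn keys; determinism is therefore a
pure function of (seed, stream, index).
"""

from __future__ import annotations

import numpy as np

_STREAMS = {
    "climate": 0,
    "gcm_bias": 1,
    "species": 2,
    "occurrence": 3,
    "ensemble": 4,
    "cv": 5,
    "misc": 6,
}


def child_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Return the deterministic child generator for a named stream."""
    try:
        key = _STREAMS[stream]
    except KeyError:  # pragma: no cover - programmer error
        raise KeyError(f"unknown random stream {stream!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key, int(index)))
    return np.random.default_rng(ss)


def child_seed(seed: int, stream: str, index: int = 0) -> int:
    """A plain integer seed (< 2**31) derived from a named stream.

    Used where third-party estimators want an ``int`` random_state.
    """
    return int(child_rng(seed, stream, index).integers(0, 2**31 - 1))
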