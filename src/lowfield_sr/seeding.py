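"""Deterministic fan-out of one master seed into named substreams.

Every stochastic component of the pipeline (phantom geometry, k-space noise,
weight initialization, patch sampling, shuffling) draws from its own named
stream so that any stage can be rerun independently and bit-reproducibly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_seed", "stream_rng"]


def stream_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit seed for the named substream.

    The mapping is pure: the same ``(master_seed, name)`` pair always yields
    the same seed, and distinct names yield statistically independent streams
    (via :class:`numpy.random.SeedSequence` entropy mixing).
    """
    if not isinstance(master_seed, (int, np.integer)):
        raise ValueError(f"master_seed must be an integer, got {type(master_seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(tag,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def stream_rng(master_seed: int, name: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for the named substream."""
    return np.random.default_rng(stream_seed(master_seed, name))
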