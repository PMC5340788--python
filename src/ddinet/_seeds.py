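"""Deterministic sub-seed derivation.

Every stochastic step in the package (negative sampling, fold shuffling,
resampling replicates, synthetic-universe generation) draws its random
state from a sub-seed derived from one master seed, so a whole pipeline is
replayable from a single integer.  Derivation is a splitmix64 hash of the
master seed and a short string tag, truncated to 31 bits so derived seeds
remain small portable integers.
"""

from __future__ import annotations

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64


def derive_seed(master: int, *tags: object) -> int:
    """Derive a 31-bit sub-seed from ``master`` and a sequence of tags.

    Tags may be strings or integers; the same (master, tags) always yields
    the same sub-seed, and distinct tags yield (with overwhelming
    probability) distinct streams.
    """
    state = _splitmix64(int(master) & _MASK64)
    for tag in tags:
        if isinstance(tag, int):
            state = _splitmix64(state ^ (tag & _MASK64))
        else:
            for byte in str(tag).encode("utf-8"):
                state = _splitmix64(state ^ byte)
    return state & 0x7FFFFFFF
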