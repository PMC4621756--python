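"""Deterministic seed derivation.

Every stochastic routine in the package takes a single integer seed and
derives independent sub-streams from it, so that a whole pipeline run is
reproducible from one number.  String parts (stage names) are folded in via
CRC32 so derivation does not depend on Python's per-process hash salt.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def _as_entropy(part: int | str) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    return int(part) & 0xFFFFFFFF


def derive_seed(*parts: int | str) -> int:
    """Derive a child seed (< 2**31) from an ordered tuple of parts."""
    if not parts:
        raise ValueError("at least one seed part is required")
    ss = np.random.SeedSequence([_as_entropy(p) for p in parts])
    return int(ss.generate_state(1)[0] % _MOD)


def rng_from(*parts: int | str) -> np.random.Generator:
    """A numpy Generator seeded from derive_seed(*parts)."""
    return np.random.default_rng(derive_seed(*parts))
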