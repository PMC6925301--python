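"""Deterministic seed derivation.

One global seed expands into independent per-module / per-repeat / per-fold
seeds through ``numpy.random.SeedSequence`` hashing of integer paths; no
module ever reads global random state.  Derived seeds stay below 2^31 so
they are valid for every downstream library.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(*parts: int | str) -> int:
    """Hash a path of ints/strings into a reproducible seed in [0, 2^31)."""
    ints = [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts
    ]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % 2**31)
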