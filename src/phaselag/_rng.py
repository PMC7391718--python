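"""Stable seed derivation for per-subject / per-session substreams."""

from __future__ import annotations

import numpy as np

_MOD = 2**31


def derive_seed(base_seed: int, *keys) -> int:
    """Derive a child seed from ``base_seed`` and a tuple of integer keys.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so the mapping is
    stable across processes and platforms and children for distinct key
    tuples are statistically independent.
    """
    spawn_key = tuple(int(k) for k in keys)
    ss = np.random.SeedSequence(int(base_seed), spawn_key=spawn_key)
    return int(ss.generate_state(1)[0] % _MOD)
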