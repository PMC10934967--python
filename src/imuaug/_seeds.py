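"""Deterministic seed derivation.

All randomness in the package flows through :func:`child_seed` /
:func:`child_rng`: a base seed plus a tuple of integer keys (subject index,
class id, repetition, copy number, ...) is hashed through
``numpy.random.SeedSequence``, giving independent, reproducible streams
without any global state.
"""

from __future__ import annotations

import numpy as np


def child_seed(base: int, *keys: int) -> int:
    """A 31-bit seed deterministically derived from ``base`` and ``keys``."""
    ss = np.random.SeedSequence(entropy=[int(base), *(int(k) for k in keys)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(base: int, *keys: int) -> np.random.Generator:
    """Independent generator for the stream identified by ``keys``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(base), *(int(k) for k in keys)])
    )
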