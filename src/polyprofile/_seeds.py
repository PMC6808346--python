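"""Deterministic child-seed derivation from a single master seed.

Every stochastic operation in the package draws its generator through
:func:`rng_for`, so the whole pipeline is reproducible from one integer
while stages remain statistically independent of one another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def _tag_int(tag: str) -> int:
    digest = hashlib.blake2s(tag.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little") & 0x7FFFFFFF


def child_seed(master: int, *tags: str) -> np.random.SeedSequence:
    """Derive a SeedSequence from ``master`` and a stable set of string tags."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *(_tag_int(t) for t in tags)])


def rng_for(master: int, *tags: str) -> np.random.Generator:
    """A fresh Generator keyed by the master seed and the operation name(s)."""
    return np.random.default_rng(child_seed(master, *tags))
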