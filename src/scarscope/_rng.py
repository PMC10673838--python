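"""Named random substreams derived from a single top-level seed.

Every stochastic stage draws from its own substream so that one stage can be
regenerated without perturbing the draws of any other.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable hash of ``names``.

    Same (seed, names) always yields the same stream; different names yield
    statistically independent streams.
    """
    key = [int(seed)] + [_name_key(str(n)) for n in names]
    return np.random.default_rng(key)
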