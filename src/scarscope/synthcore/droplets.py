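"""Droplet positivity draws under Poisson occupancy."""

from __future__ import annotations

import math

from .._rng import substream
from ..reporterquant.ddpcr import DropletCount

__all__ = ["gen_droplets"]


def gen_droplets(
    true_lambda: float,
    n_droplets: int,
    seed: int = 0,
    droplet_volume_nl: float = 0.85,
) -> DropletCount:
    """Draw positives ~ Binomial(n_droplets, 1 - exp(-true_lambda)).

    ``true_lambda`` is the mean template copies per droplet.
    """
    if true_lambda < 0:
        raise ValueError("true_lambda must be >= 0")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    rng = substream(seed, "droplets")
    p_pos = -math.expm1(-true_lambda)
    positives = int(rng.binomial(n_droplets, p_pos))
    return DropletCount(positives=positives, total=n_droplets, droplet_volume_nl=droplet_volume_nl)
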