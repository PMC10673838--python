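"""Draw Mendelian offspring genotype counts with genotype-specific lethality."""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .._rng import substream
from ..crossstats.mendel import CrossSpec, genotype_distribution

__all__ = ["gen_cross_counts"]


def gen_cross_counts(
    cross: CrossSpec,
    n_offspring: int,
    lethal_penetrance: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``n_offspring`` conceptuses from the Mendelian genotype
    distribution, thin each by its genotype's survival probability, and
    tabulate surviving counts per genotype.

    ``lethal_penetrance`` maps genotype label -> survival probability
    (default 1 for unlisted genotypes). Returns a table with columns
    genotype, observed (all genotypes listed, zeros included).
    """
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    lethal_penetrance = dict(lethal_penetrance or {})
    for g, p in lethal_penetrance.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"survival probability for {g!r} must be in [0, 1]")

    dist = genotype_distribution(cross)  # label -> Fraction, pre-lethality
    labels = list(dist)
    probs = [float(dist[g]) for g in labels]

    rng = substream(seed, "cross_counts")
    counts = dict.fromkeys(labels, 0)
    if n_offspring > 0:
        drawn = rng.multinomial(n_offspring, probs)
        for label, n in zip(labels, drawn):
            surv = lethal_penetrance.get(label, 1.0)
            if surv >= 1.0:
                counts[label] = int(n)
            elif surv <= 0.0:
                counts[label] = 0
            else:
                counts[label] = int(rng.binomial(n, surv))
    return pd.DataFrame({"genotype": labels, "observed": [counts[g] for g in labels]})
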