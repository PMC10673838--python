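"""Goodness-of-fit tests for cross tables and marker-count normalization."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["gof_chisq", "binomial_genotype_test", "marker_normalize"]


def gof_chisq(
    observed: Sequence[int] | Mapping[str, int],
    expected_proportions: Sequence[float] | Mapping[str, float],
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit of observed counts against expected
    proportions. Returns ``(chi2, df, p)`` with ``df = categories - 1`` and an
    upper-tail p-value.

    When both arguments are mappings they are aligned by key.
    """
    if isinstance(observed, Mapping):
        if isinstance(expected_proportions, Mapping):
            keys = list(observed)
            missing = [k for k in keys if k not in expected_proportions]
            if missing:
                raise ValueError(f"expected proportions missing categories: {missing}")
            expected_proportions = [expected_proportions[k] for k in keys]
        observed = list(observed.values())
    elif isinstance(expected_proportions, Mapping):
        expected_proportions = list(expected_proportions.values())

    obs = np.asarray(observed, dtype=float)
    props = np.asarray([float(p) for p in expected_proportions], dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if obs.size != props.size:
        raise ValueError("observed and expected category counts differ")
    if np.any(props <= 0):
        raise ValueError("expected proportions must be > 0")
    total = obs.sum()
    if total == 0:
        raise ValueError("total observed count is zero")
    props = props / props.sum()

    exp = props * total
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def binomial_genotype_test(observed_k: int, n: int, p0: float) -> tuple[float, float]:
    """Chi-square GOF on the two categories {genotype, not-genotype} with
    expected proportions {p0, 1-p0} (df=1, no continuity correction).
    Returns ``(chi2, p)``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= observed_k <= n:
        raise ValueError("observed_k must satisfy 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    chi2, _, p = gof_chisq([observed_k, n - observed_k], [p0, 1.0 - p0])
    return chi2, p


def marker_normalize(marker_count: float, total_chromosomes: int) -> float:
    """Marker-chromosome count normalized to a 40-chromosome metaphase."""
    if total_chromosomes <= 0:
        raise ValueError("total_chromosomes must be > 0")
    return marker_count * 40.0 / total_chromosomes
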