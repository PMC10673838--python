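"""Parameter records and size-distribution primitives for the generators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ScarSimParams", "EndSeqSimParams", "draw_sizes", "point_mass", "geometric", "empirical"]


def point_mass(value: int) -> dict:
    return {"name": "point", "value": int(value)}


def geometric(mean: float) -> dict:
    """Geometric on {1, 2, ...} with the given mean (p = 1/mean)."""
    return {"name": "geometric", "mean": float(mean)}


def empirical(values: Sequence[int], probs: Sequence[float] | None = None) -> dict:
    return {"name": "empirical", "values": list(values), "probs": None if probs is None else list(probs)}


def draw_sizes(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    """Draw ``n`` non-negative integer sizes from a named distribution."""
    name = dist["name"]
    if name == "point":
        return np.full(n, int(dist["value"]), dtype=int)
    if name == "geometric":
        mean = float(dist["mean"])
        if mean < 1:
            raise ValueError("geometric mean must be >= 1")
        return rng.geometric(1.0 / mean, size=n).astype(int)
    if name == "empirical":
        return rng.choice(np.asarray(dist["values"], dtype=int), size=n, p=dist.get("probs"))
    if name == "poisson":
        return rng.poisson(float(dist["mean"]), size=n).astype(int)
    raise ValueError(f"unknown size distribution {name!r}")


def _check_prob(x: float, what: str) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{what} must be in [0, 1], got {x}")
    return float(x)


@dataclass(frozen=True)
class ScarSimParams:
    """Parameters for the junction-read generator."""

    n_reads: int
    deletion_size_dist: Mapping = field(default_factory=lambda: geometric(20.0))
    mh_propensity: float = 0.5       # P(a deletion is deliberately placed at a microhomology)
    insertion_rate: float = 0.0      # P(a non-templated insertion at the junction)
    insertion_length_dist: Mapping = field(default_factory=lambda: geometric(2.0))
    read_trim: int = 0               # max bases removed from each outer read end
    min_mh: int = 2                  # minimum repeat length that counts as an MH placement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_trim < 0:
            raise ValueError("read_trim must be >= 0")
        _check_prob(self.mh_propensity, "mh_propensity")
        _check_prob(self.insertion_rate, "insertion_rate")


@dataclass(frozen=True)
class EndSeqSimParams:
    """Parameters for the strand-resolved end-count track generator."""

    sites: Mapping[str, Sequence[int]]   # chrom -> motif start positions (0-based)
    mean_resection_bp: float | Mapping[tuple[str, int], float] = 1000.0
    reads_per_site: int = 1000
    background_rate: float = 0.0         # expected background reads per kb
    strand_model: bool = False           # emit separate plus/minus end tracks
    endpoint_dist: str = "exponential"   # or "gamma"
    gamma_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_site < 0:
            raise ValueError("reads_per_site must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.endpoint_dist not in ("exponential", "gamma"):
            raise ValueError("endpoint_dist must be 'exponential' or 'gamma'")
        means = (
            self.mean_resection_bp.values()
            if isinstance(self.mean_resection_bp, Mapping)
            else [self.mean_resection_bp]
        )
        if any(m <= 0 for m in means):
            raise ValueError("mean_resection_bp must be > 0")

    def mean_for(self, chrom: str, pos: int) -> float:
        if isinstance(self.mean_resection_bp, Mapping):
            return float(self.mean_resection_bp[(chrom, pos)])
        return float(self.mean_resection_bp)
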