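"""Digital droplet PCR quantification: Poisson occupancy inversion and the
HR / TMEJ reporter scores."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = ["DropletCount", "ReporterResult", "ddpcr_concentration", "hr_score", "tmej_score",
           "TMEJ_PRODUCTS"]

TMEJ_PRODUCTS = ("del23bp", "del39bp", "del95bp")


@dataclass(frozen=True)
class DropletCount:
    positives: int
    total: int
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total droplets must be > 0")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must satisfy 0 <= positives <= total")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be > 0")

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.total


@dataclass(frozen=True)
class ReporterResult:
    hr_percent: float | None = None      # repair copies per 100 genomic copies
    tmej_products: Mapping[str, float] | None = None
    tmej_norm: float | None = None       # ratio to the reference (wild-type) sample


def ddpcr_concentration(d: DropletCount) -> float:
    """Copies per microliter from droplet positivity.

    Inverts Poisson occupancy: lambda = -ln(1 - positives/total) copies per
    droplet, divided by the droplet volume. A saturated assay (all droplets
    positive) has unbounded concentration and raises.
    """
    if d.positives == d.total:
        raise ValueError("all droplets positive: assay saturated, concentration unbounded")
    lam = -math.log1p(-d.positive_fraction)
    volume_ul = d.droplet_volume_nl * 1e-3
    return lam / volume_ul


def _copies(x: float | DropletCount) -> float:
    """Accept direct copy numbers or DropletCounts (converted to lambda-scale
    copies per droplet x total, proportional to absolute copies)."""
    if isinstance(x, DropletCount):
        if x.positives == x.total:
            raise ValueError("saturated droplet count")
        return -math.log1p(-x.positive_fraction) * x.total
    return float(x)


def hr_score(repair_copies: float | DropletCount, genomic_control_copies: float | DropletCount) -> float:
    """HR repair copies as a percentage of genomic DNA copies."""
    control = _copies(genomic_control_copies)
    if control <= 0:
        raise ValueError("genomic control copies must be > 0")
    return 100.0 * _copies(repair_copies) / control


def tmej_score(products: Mapping[str, float | DropletCount], reference_sum: float) -> float:
    """Sum of the three signature deletion products normalized to a reference
    sample's sum. Raises listing any missing product."""
    missing = [k for k in TMEJ_PRODUCTS if k not in products]
    if missing:
        raise ValueError(f"missing TMEJ product entries: {missing}")
    if reference_sum <= 0:
        raise ValueError("reference_sum must be > 0")
    return sum(_copies(products[k]) for k in TMEJ_PRODUCTS) / reference_sum
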