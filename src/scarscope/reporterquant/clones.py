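"""CRISPR clone genotype binning by per-allele frameshift status.

An allele's classification follows its net indel length: 0 is wild-type, a
multiple of 3 is in-frame, anything else is a frameshift. Compound alleles
use the summed net length. A clone is a knockout only when every reported
allele is frameshift; clones with no edited allele are unedited and excluded
from the knockout-fraction denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["AlleleCall", "classify_clone", "ko_fraction", "REPORTING_FLOOR"]

REPORTING_FLOOR = 0.01  # allele frequencies at or below this are not reported


@dataclass(frozen=True)
class AlleleCall:
    net_indel_length: int           # signed bp; 0 = unedited
    allele_frequency: float = 1.0   # fraction of reads supporting the allele

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError("allele_frequency must be in [0, 1]")

    @property
    def classification(self) -> str:
        if self.net_indel_length == 0:
            return "wildtype"
        return "in_frame" if self.net_indel_length % 3 == 0 else "frameshift"


def classify_clone(
    alleles: Sequence[AlleleCall], reporting_floor: float = REPORTING_FLOOR
) -> str:
    """Bin one clone as 'knockout', 'retains_function', or 'unedited'.

    Alleles at or below the reporting floor are dropped first; an empty
    remaining list raises.
    """
    kept = [a for a in alleles if a.allele_frequency > reporting_floor]
    if not kept:
        raise ValueError("no alleles above the reporting floor")
    classes = {a.classification for a in kept}
    if classes == {"frameshift"}:
        return "knockout"
    if classes == {"wildtype"}:
        return "unedited"
    return "retains_function"


def ko_fraction(clones: Iterable[Sequence[AlleleCall] | str]) -> tuple[float, dict[str, int]]:
    """Knockout fraction among edited clones, plus per-bin counts.

    Accepts either raw allele lists or pre-computed bin labels. Unedited
    clones are excluded from the denominator; zero edited clones raises.
    """
    counts = {"knockout": 0, "retains_function": 0, "unedited": 0}
    for clone in clones:
        label = clone if isinstance(clone, str) else classify_clone(clone)
        if label not in counts:
            raise ValueError(f"unknown clone bin {label!r}")
        counts[label] += 1
    edited = counts["knockout"] + counts["retains_function"]
    if edited == 0:
        raise ValueError("no edited clones: knockout fraction undefined")
    return counts["knockout"] / edited, counts
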