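"""Restriction-motif site discovery and track normalization."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["MotifSite", "find_motif_sites", "normalize_track", "DEFAULT_MOTIF"]

DEFAULT_MOTIF = "GCGATCGC"  # palindromic 8-mer: a forward-strand scan is complete


@dataclass(frozen=True, order=True)
class MotifSite:
    chrom: str
    pos: int  # 0-based start of the motif

    @property
    def site_center(self) -> int:
        return self.pos + 4


def find_motif_sites(
    genome: Mapping[str, str], motif: str = DEFAULT_MOTIF
) -> list[MotifSite]:
    """Every exact forward-strand occurrence of ``motif``, sorted by
    (chrom, pos). For palindromic motifs (the default is its own reverse
    complement) this equals the deduplicated both-strand site set.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    sites: list[MotifSite] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        start = seq.find(motif)
        while start != -1:
            sites.append(MotifSite(chrom=chrom, pos=start))
            start = seq.find(motif, start + 1)
    return sites


def normalize_track(
    track: Mapping[str, np.ndarray], library_size: float
) -> dict[str, np.ndarray]:
    """Scale raw end counts to reads per million (RPM)."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return {c: np.asarray(v, dtype=float) * (1e6 / library_size) for c, v in track.items()}
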