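"""Binned signal profiles around motif sites."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .motifs import MotifSite

__all__ = ["SiteProfile", "bin_signal"]

DEFAULT_WINDOW = 20_000
DEFAULT_BIN_SIZE = 250

Track = Mapping[str, np.ndarray]
StrandedTrack = Mapping[str, Mapping[str, np.ndarray]]


def _is_stranded(track) -> bool:
    first = next(iter(track.values()), None)
    return isinstance(first, Mapping)


@dataclass
class SiteProfile:
    """Signal summed into fixed-width bins covering
    ``[center - window, center + window)`` around one motif site.

    With a strand-resolved input, ``bins`` holds the combined signal and
    ``bins_minus``/``bins_plus`` the per-strand components (minus-strand ends
    fall left of a cut, plus-strand ends right of it).
    """

    site: MotifSite
    bin_size: int
    window: int
    bins: np.ndarray
    bins_minus: np.ndarray | None = None
    bins_plus: np.ndarray | None = None
    normalized: bool = False
    edge_truncated: bool = False
    is_cut: bool | None = None
    peak_height: float = field(default=float("nan"))

    @property
    def n_bins(self) -> int:
        return 2 * self.window // self.bin_size

    @property
    def bin_starts(self) -> np.ndarray:
        """Genomic start of each bin."""
        center = self.site.site_center
        return center - self.window + self.bin_size * np.arange(self.n_bins)


def _bin_one(arr: np.ndarray, center: int, window: int, bin_size: int) -> tuple[np.ndarray, bool]:
    n_bins = 2 * window // bin_size
    bins = np.zeros(n_bins, dtype=float)
    lo = center - window
    truncated = lo < 0 or center + window > arr.size
    for b in range(n_bins):
        start = max(lo + b * bin_size, 0)
        end = min(lo + (b + 1) * bin_size, arr.size)
        if start < end:
            bins[b] = arr[start:end].sum()
    return bins, truncated


def bin_signal(
    track: Track | StrandedTrack,
    sites: Sequence[MotifSite],
    window: int = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    *,
    normalized: bool = False,
) -> list[SiteProfile]:
    """Sum track signal into half-open genomic bins around each site.

    ``window`` must be divisible by ``bin_size``. Bins extending past a contig
    edge contribute 0 and flag the profile as edge-truncated (with a warning).
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    stranded = _is_stranded(track)
    profiles = []
    for site in sites:
        if site.chrom not in track:
            raise ValueError(f"site chrom {site.chrom!r} absent from track")
        center = site.site_center
        if stranded:
            minus, t1 = _bin_one(np.asarray(track[site.chrom]["-"]), center, window, bin_size)
            plus, t2 = _bin_one(np.asarray(track[site.chrom]["+"]), center, window, bin_size)
            bins, truncated = minus + plus, t1 or t2
            prof = SiteProfile(site=site, bin_size=bin_size, window=window, bins=bins,
                               bins_minus=minus, bins_plus=plus, normalized=normalized,
                               edge_truncated=truncated)
        else:
            bins, truncated = _bin_one(np.asarray(track[site.chrom]), center, window, bin_size)
            prof = SiteProfile(site=site, bin_size=bin_size, window=window, bins=bins,
                               normalized=normalized, edge_truncated=truncated)
        if truncated:
            warnings.warn(
                f"window around {site.chrom}:{site.pos} exits the contig; "
                "out-of-bounds bins filled with 0", stacklevel=2,
            )
        profiles.append(prof)
    return profiles
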