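"""Per-coordinate deletion / microhomology frequency profiles around the junction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import JunctionCall
from .template import JunctionTemplate

__all__ = ["PositionProfile", "position_profiles"]


@dataclass(frozen=True)
class PositionProfile:
    """Deletion and MH coverage frequencies at product coordinates relative to
    the junction j (coordinate 0 = first parent-B base)."""

    coords: np.ndarray      # relative coordinates, ..., -2, -1, 0, 1, ...
    del_freq: np.ndarray    # fraction of reads whose deletion interval covers the coordinate
    mh_freq: np.ndarray     # fraction of reads whose mh_span covers the coordinate
    n_reads: int            # non-excluded reads

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_coord": self.coords, "del_freq": self.del_freq, "mh_freq": self.mh_freq}
        )


def position_profiles(
    calls: Sequence[JunctionCall],
    template: JunctionTemplate,
    window: int = 50,
) -> PositionProfile:
    """Coverage-count deletion and MH intervals over ``[j - window, j + window)``.

    Frequencies are per-coordinate fractions of non-excluded reads whose
    deletion interval (resp. mh_span) covers that product coordinate.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    kept = [c for c in calls if not c.excluded]
    if not kept:
        raise ValueError("no non-excluded calls to profile")

    j = template.junction_pos
    coords = np.arange(-window, window)
    abs_coords = coords + j
    del_counts = np.zeros(coords.size, dtype=float)
    mh_counts = np.zeros(coords.size, dtype=float)
    for c in kept:
        del_counts += (abs_coords >= c.del_start) & (abs_coords < c.del_end)
        if c.mh_len > 0:
            mh_counts += (abs_coords >= c.mh_start) & (abs_coords < c.mh_end)
    n = len(kept)
    return PositionProfile(coords=coords, del_freq=del_counts / n, mh_freq=mh_counts / n, n_reads=n)
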