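"""Well-grid translocation frequency.

A plate condition is scored from a rectangular well x technical-replicate
boolean grid of "translocation product detected" calls. The positivity rule
is configurable because the underlying phrasing ("total number of
translocation-positive wells across both technical replicates") is ambiguous:

- ``any`` (default): a well is positive if detected in >= 1 replicate
- ``all``: positive only if detected in every replicate
- ``sum``: each (well, replicate) entry counts independently
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WellGrid", "translocation_frequency"]

_RULES = ("any", "all", "sum")


@dataclass(frozen=True)
class WellGrid:
    condition: str
    detected: np.ndarray  # bool, shape (n_wells, n_replicates)

    def __post_init__(self) -> None:
        arr = np.asarray(self.detected, dtype=bool)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("well grid must be a rectangular 2D array with >= 1 well")
        object.__setattr__(self, "detected", arr)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "") -> "WellGrid":
        """Build from a long-format table with columns well, replicate, detected."""
        pivot = df.pivot_table(index="well", columns="replicate", values="detected", aggfunc="first")
        if pivot.isna().any().any():
            raise ValueError("well grid is not rectangular: missing (well, replicate) entries")
        return cls(condition=condition, detected=pivot.to_numpy(dtype=bool))


def translocation_frequency(grid: WellGrid, rule: str = "any") -> float:
    """Percent of translocation-positive wells under the given positivity rule."""
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}, got {rule!r}")
    det = grid.detected
    if rule == "any":
        return 100.0 * det.any(axis=1).mean()
    if rule == "all":
        return 100.0 * det.all(axis=1).mean()
    return 100.0 * det.mean()
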