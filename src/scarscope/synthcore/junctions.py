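"""Generate junction reads carrying junction-proximal deletion/insertion scars.

Each read is the predicted translocation product modified by one contiguous
deletion whose interval intersects the closed breakpoint-adjacent window
``[j-1, j+1]`` (junction PCR only recovers junction-proximal scars), plus an
optional non-templated insertion at the deletion site. When a microhomology
event is drawn, the deletion is placed at a flanking repeat (junction-shift
ambiguity >= ``min_mh``) if the product offers one; otherwise placement falls
back to a uniform junction-proximal draw.

The truth table records the generative scar. Microhomology truth is measured
on the placed deletion by brute-force placement equivalence (every deletion
start producing an identical repaired sequence), so re-measuring a generated
read recovers the truth row exactly.
"""

from __future__ import annotations

import pandas as pd

from .._rng import substream
from ..junctionscan.template import JunctionTemplate
from .params import ScarSimParams, draw_sizes

__all__ = ["gen_junction_reads", "placement_ambiguity"]

_BASES = "ACGT"
_MAX_REDRAWS = 1000


def placement_ambiguity(product: str, start: int, d: int) -> tuple[int, int, int]:
    """Junction-shift ambiguity of deleting ``[start, start+d)`` from ``product``.

    Returns ``(mh_len, span_start, span_end)`` where ``[span_start, span_end)``
    is the half-open interval of equivalent deletion start positions; its
    length is the microhomology length. Brute force by string equality.
    """
    if d == 0:
        return 0, start, start
    target = product[:start] + product[start + d:]
    starts = [
        u for u in range(len(product) - d + 1)
        if product[:u] + product[u + d:] == target
    ]
    return max(starts) - min(starts), min(starts), max(starts)


def _placement_range(L: int, j: int, d: int) -> tuple[int, int]:
    """Inclusive range of deletion starts whose interval [u, u+d) intersects
    the closed window [j-1, j+1]."""
    lo = max(0, j - d)
    hi = min(L - d, j + 1)
    return lo, hi


def gen_junction_reads(
    template: JunctionTemplate, params: ScarSimParams
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Return ``(reads, truth)``: a list of (read_id, sequence) pairs and a
    one-row-per-read ground-truth table.

    Deletions larger than the product (or with no junction-proximal placement)
    are rejected and redrawn. Insertion sequences are redrawn if their boundary
    bases coincide with the adjacent product bases, so each generated scar has
    a unique anchored decomposition and classification recovers the truth.
    """
    rng = substream(params.seed, "junction_reads")
    product = template.product_seq
    L = len(product)
    j = template.junction_pos

    reads: list[tuple[str, str]] = []
    rows: list[dict] = []
    for i in range(params.n_reads):
        # --- deletion size ---
        d = -1
        for _ in range(_MAX_REDRAWS):
            cand = int(draw_sizes(rng, params.deletion_size_dist, 1)[0])
            if cand <= L:
                lo, hi = _placement_range(L, j, cand)
                if lo <= hi:
                    d = cand
                    break
        if d < 0:
            raise ValueError("could not draw a deletion size fitting the product")

        # --- deletion placement ---
        if d == 0:
            start = j
            at_mh = False
        else:
            lo, hi = _placement_range(L, j, d)
            at_mh = bool(rng.random() < params.mh_propensity)
            start = -1
            if at_mh:
                candidates = [
                    u for u in range(lo, hi + 1)
                    if placement_ambiguity(product, u, d)[0] >= params.min_mh
                ]
                if candidates:
                    start = int(rng.choice(candidates))
                else:
                    at_mh = False  # no repeat available: fall back to non-MH placement
            if start < 0:
                start = int(rng.integers(lo, hi + 1))
        mh_len, mh_start, mh_end = placement_ambiguity(product, start, d)

        # --- optional non-templated insertion ---
        insertion = ""
        if rng.random() < params.insertion_rate:
            ins_len = max(1, int(draw_sizes(rng, params.insertion_length_dist, 1)[0]))
            # the prefix anchor would absorb insertion[0] if it equals
            # product[start]; the suffix anchor would absorb insertion[-1] if
            # it equals product[start+d-1]
            after_p = product[start] if start < L else None
            before_s = product[start + d - 1] if start + d > 0 else None
            for _ in range(_MAX_REDRAWS):
                insertion = "".join(rng.choice(list(_BASES), size=ins_len))
                if after_p is not None and insertion[0] == after_p:
                    continue
                if before_s is not None and insertion[-1] == before_s:
                    continue
                break
            else:
                raise ValueError("could not draw an unambiguous insertion sequence")

        read = product[:start] + insertion + product[start + d:]

        # --- outer end trimming ---
        trim5 = int(rng.integers(0, params.read_trim + 1)) if params.read_trim else 0
        trim3 = int(rng.integers(0, params.read_trim + 1)) if params.read_trim else 0
        read = read[trim5: len(read) - trim3] if trim3 else read[trim5:]

        rid = f"read_{i:05d}"
        reads.append((rid, read))
        rows.append(
            {
                "read_id": rid,
                "d": d,
                "del_start": start,
                "del_end": start + d,
                "insertion": insertion,
                "mh_len": mh_len,
                "mh_start": mh_start,
                "mh_end": mh_end,
                "at_mh": at_mh,
                "trim5": trim5,
                "trim3": trim3,
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "d", "del_start", "del_end", "insertion",
            "mh_len", "mh_start", "mh_end", "at_mh", "trim5", "trim3",
        ],
    )
    return reads, truth
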