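"""Per-read scar classification against a predicted junction product.

A read is decomposed into the longest exactly-matching prefix and suffix
anchors against the product; whatever the anchors do not explain is a
deletion (missing product bases) and/or a non-templated insertion (extra read
bases). Microhomology is reported as the junction-shift ambiguity of the
deletion within the product: the number of alternative deletion placements
yielding an identical repaired sequence.

Degenerate bases: ``N`` matches nothing. Reads with an N within 1 bp of the
junction, or with an anchor shorter than ``min_anchor``, are returned with
``excluded=True`` (mirroring exclusion of unresolvable mixed traces).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .template import JunctionTemplate

__all__ = ["JunctionCall", "classify_junction", "classify_reads", "deletion_sizes", "calls_to_frame"]

DEFAULT_MIN_ANCHOR = 10


@dataclass(frozen=True)
class JunctionCall:
    """One read's scar relative to the predicted product.

    Invariants (for non-excluded calls): ``d == L - p - s``,
    ``len(insertion_seq) == read_len - p - s``, ``mh_len == mh_end - mh_start``.
    """

    read_id: str
    p: int                  # prefix anchor length
    s: int                  # suffix anchor length
    d: int                  # deletion size, bp
    del_start: int          # half-open product interval [del_start, del_end)
    del_end: int
    insertion_seq: str
    mh_len: int
    mh_seq: str
    mh_start: int           # half-open product interval of junction ambiguity
    mh_end: int
    excluded: bool
    read_len: int


def _base_eq(a: str, b: str) -> bool:
    # N matches nothing, including another N
    return a == b and a != "N"


def _lcp(read: str, product: str) -> int:
    n = min(len(read), len(product))
    k = 0
    while k < n and _base_eq(read[k], product[k]):
        k += 1
    return k


def _lcs(read: str, product: str) -> int:
    n = min(len(read), len(product))
    k = 0
    while k < n and _base_eq(read[-1 - k], product[-1 - k]):
        k += 1
    return k


def classify_junction(
    read: str,
    template: JunctionTemplate,
    *,
    read_id: str = "read",
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> JunctionCall:
    """Classify one read against ``template.product_seq``.

    Anchors are maximal; if prefix+suffix over-explain the read the excess is
    assigned to the prefix (suffix reduced), so anchors never overlap within
    the read. Microhomology is computed on the deletion anchors even when an
    insertion co-occurs; calls with ``d == 0`` report ``mh_len == 0``.
    """
    read = read.upper()
    product = template.product_seq
    L, R = len(product), len(read)

    p = _lcp(read, product)
    s = _lcs(read, product)
    cap = min(R, L)
    if p + s > cap:
        s = cap - p

    d = L - p - s
    insertion = read[p: R - s]

    if d > 0:
        m_left = 0
        while m_left < p and _base_eq(product[p - m_left - 1], product[p + d - m_left - 1]):
            m_left += 1
        m_right = 0
        while m_right < s and _base_eq(product[p + m_right], product[p + d + m_right]):
            m_right += 1
        mh_start, mh_end = p - m_left, p + m_right
    else:
        mh_start = mh_end = p

    m = mh_end - mh_start
    junction_region = read[max(0, p - 1): min(R, R - s + 1)]
    excluded = p < min_anchor or s < min_anchor or "N" in junction_region

    return JunctionCall(
        read_id=read_id,
        p=p,
        s=s,
        d=d,
        del_start=p,
        del_end=p + d,
        insertion_seq=insertion,
        mh_len=m,
        mh_seq=product[mh_start:mh_end],
        mh_start=mh_start,
        mh_end=mh_end,
        excluded=excluded,
        read_len=R,
    )


def classify_reads(
    reads: Iterable[tuple[str, str]],
    template: JunctionTemplate,
    *,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[JunctionCall]:
    """Classify an iterable of ``(read_id, sequence)`` pairs."""
    return [
        classify_junction(seq, template, read_id=rid, min_anchor=min_anchor)
        for rid, seq in reads
    ]


def deletion_sizes(calls: Sequence[JunctionCall]) -> tuple[list[int], float]:
    """Per-read deletion sizes for non-excluded calls, plus the median.

    Median uses the midpoint-of-two rule for even counts (half-integers are
    possible). Raises if every call is excluded.
    """
    sizes = [c.d for c in calls if not c.excluded]
    if not sizes:
        raise ValueError("no non-excluded calls: cannot compute deletion sizes")
    return sizes, float(statistics.median(sizes))


def calls_to_frame(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    """Tabulate calls for TSV output."""
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in calls],
            "p": [c.p for c in calls],
            "s": [c.s for c in calls],
            "d": [c.d for c in calls],
            "del_start": [c.del_start for c in calls],
            "del_end": [c.del_end for c in calls],
            "insertion": [c.insertion_seq for c in calls],
            "mh_len": [c.mh_len for c in calls],
            "mh_seq": [c.mh_seq for c in calls],
            "mh_start": [c.mh_start for c in calls],
            "mh_end": [c.mh_end for c in calls],
            "excluded": [c.excluded for c in calls],
        }
    )
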