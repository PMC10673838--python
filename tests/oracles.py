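"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by enumeration/recounting, sharing no
code path with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product as iproduct


def _match_prefix(read: str, product: str, p: int) -> bool:
    seg = read[:p]
    return seg == product[:p] and "N" not in seg


def _match_suffix(read: str, product: str, s: int) -> bool:
    if s == 0:
        return True
    seg = read[-s:]
    return seg == product[-s:] and "N" not in seg


def junction_oracle(read: str, product: str) -> tuple[int, int, int, tuple[int, int]]:
    """Enumerate every anchored (p, s) decomposition, keep those with minimal
    unexplained bases, and measure the deletion's breakpoint-shift range by
    whole-string placement equality.

    Returns (deletion_size, insertion_length, mh_len, mh_span).
    """
    L, R = len(product), len(read)
    cap = min(R, L)
    valid_p = [p for p in range(cap + 1) if _match_prefix(read, product, p)]
    valid_s = [s for s in range(cap + 1) if _match_suffix(read, product, s)]
    best = max(p + s for p in valid_p for s in valid_s if p + s <= cap)
    d = L - best
    ins_len = R - best
    # tie-break mirrors the contract: excess explained by the prefix
    p_sel = max(p for p in valid_p if (best - p) in valid_s and 0 <= best - p <= cap)

    if d == 0:
        return d, ins_len, 0, (p_sel, p_sel)
    target = product[:p_sel] + product[p_sel + d:]
    starts = [u for u in range(L - d + 1) if product[:u] + product[u + d:] == target]
    return d, ins_len, max(starts) - min(starts), (min(starts), max(starts))


def motif_scan_oracle(seq: str, motif: str) -> list[int]:
    """Naive sliding-window motif scan."""
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i:i + len(motif)] == motif]


def bin_recount_oracle(arr, center: int, window: int, bin_size: int) -> list[float]:
    """Per-base recount of binned sums, bins half-open, truncated at edges."""
    out = []
    for b in range(2 * window // bin_size):
        start = center - window + b * bin_size
        end = start + bin_size
        total = 0.0
        for pos in range(max(start, 0), min(end, len(arr))):
            total += float(arr[pos])
        out.append(total)
    return out


def gamete_enumeration_oracle(loci, parent1, parent2, lethal=()):
    """Exhaustive enumeration over all parental gamete combinations (4^loci
    outcomes, each weighted (1/4)^loci), thinned by lethal-predicate survival
    and renormalized. Returns {label: Fraction}.
    """
    n = len(loci)
    weights: dict[str, Fraction] = {}
    gametes1 = iproduct(*[parent1[l] for l in loci])
    for g1 in gametes1:
        for g2 in iproduct(*[parent2[l] for l in loci]):
            label = ";".join("".join(sorted((a1, a2))) for a1, a2 in zip(g1, g2))
            weights[label] = weights.get(label, Fraction(0)) + Fraction(1, 4**n)
    thinned: dict[str, Fraction] = {}
    for label, w in weights.items():
        genotype = dict(zip(loci, label.split(";")))
        surv = Fraction(1)
        for predicate, fraction in lethal:
            if all(genotype.get(l) == g for l, g in predicate.items()):
                surv *= Fraction(fraction).limit_denominator(10**6)
        if surv > 0:
            thinned[label] = w * surv
    total = sum(thinned.values())
    return {label: w / total for label, w in thinned.items()}


def profile_recount_oracle(intervals, j: int, window: int, n_reads: int) -> list[float]:
    """Per-coordinate recount of interval coverage frequencies."""
    freqs = []
    for rel in range(-window, window):
        coord = j + rel
        covered = sum(1 for start, end in intervals if start <= coord < end)
        freqs.append(covered / n_reads)
    return freqs
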