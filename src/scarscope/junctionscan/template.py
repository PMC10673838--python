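"""Predicted translocation products from two parental loci.

A blunt fusion joins the left piece of parent A (bases ``[0, cut_a)``) to the
right piece of parent B (bases ``[cut_b, len)``). Cut positions may be given
directly or derived from Cas9 protospacers, in which case the blunt cut falls
between protospacer positions 17 and 18 (3 bp 5' of the NGG PAM), on either
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["JunctionTemplate", "build_predicted_junction", "find_guide_cut", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class JunctionTemplate:
    """Two parental sequences, their cut offsets, and the fused product.

    ``product_seq = parent_a_seq[:cut_a] + parent_b_seq[cut_b:]`` and the
    junction coordinate ``j`` (first parent-B base of the product) equals
    ``cut_a``. All coordinates 0-based.
    """

    parent_a_seq: str
    parent_b_seq: str
    cut_a: int
    cut_b: int
    product_seq: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_a_seq", _check_dna(self.parent_a_seq, "parent_a_seq"))
        object.__setattr__(self, "parent_b_seq", _check_dna(self.parent_b_seq, "parent_b_seq"))
        if not 0 <= self.cut_a <= len(self.parent_a_seq):
            raise ValueError(f"cut_a={self.cut_a} outside parent_a [0, {len(self.parent_a_seq)}]")
        if not 0 <= self.cut_b <= len(self.parent_b_seq):
            raise ValueError(f"cut_b={self.cut_b} outside parent_b [0, {len(self.parent_b_seq)}]")
        object.__setattr__(
            self, "product_seq", self.parent_a_seq[: self.cut_a] + self.parent_b_seq[self.cut_b:]
        )

    @property
    def junction_pos(self) -> int:
        """Product coordinate of the fusion point (index of first parent-B base)."""
        return self.cut_a


def find_guide_cut(parent: str, guide: str) -> int:
    """Locate a 20-nt protospacer in ``parent`` (either strand) and return the
    blunt cut offset: 3 bp 5' of the PAM, between protospacer bases 17 and 18.

    The guide must occur exactly once across both strands and carry an
    adjacent NGG PAM; otherwise a ValueError names the guide.
    """
    parent = _check_dna(parent, "parent")
    guide = _check_dna(guide, "guide")
    if len(guide) != 20:
        raise ValueError(f"guide {guide} is {len(guide)} nt; expected a 20-nt protospacer")

    hits: list[tuple[int, str]] = []
    for strand, probe in (("+", guide), ("-", revcomp(guide))):
        start = parent.find(probe)
        while start != -1:
            hits.append((start, strand))
            start = parent.find(probe, start + 1)
    if not hits:
        raise ValueError(f"guide {guide} not found in parent sequence")
    if len(hits) > 1:
        raise ValueError(f"guide {guide} matches the parent {len(hits)} times; expected once")

    pos, strand = hits[0]
    if strand == "+":
        pam = parent[pos + 20: pos + 23]
        if len(pam) != 3 or pam[1:] != "GG":
            raise ValueError(f"guide {guide}: no NGG PAM adjacent to the protospacer")
        return pos + 17
    pam = parent[max(pos - 3, 0): pos]
    if len(pam) != 3 or pam[:2] != "CC":
        raise ValueError(f"guide {guide}: no NGG PAM adjacent to the protospacer")
    return pos + 3


def build_predicted_junction(
    parent_a: str,
    parent_b: str,
    guide_a: str | None = None,
    guide_b: str | None = None,
    *,
    cut_a: int | None = None,
    cut_b: int | None = None,
) -> JunctionTemplate:
    """Build the predicted blunt-fusion product from guides or explicit cuts.

    Each cut may be given either as a guide (Cas9 17/18 rule applied) or as an
    explicit offset; explicit offsets take precedence.
    """
    if cut_a is None:
        if guide_a is None:
            raise ValueError("provide guide_a or cut_a")
        cut_a = find_guide_cut(parent_a, guide_a)
    if cut_b is None:
        if guide_b is None:
            raise ValueError("provide guide_b or cut_b")
        cut_b = find_guide_cut(parent_b, guide_b)
    return JunctionTemplate(parent_a, parent_b, cut_a, cut_b)
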